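# Methods

This note documents the models, conventions and design choices behind
`vrdphylo`. The package reconstructs the evolutionary history of viral
RNA-dependent polymerases (vRdPs) from structural information: a curated
study set of polymerase crystal structures, their pairwise structural
similarities, a structure-based multiple alignment, a discrete coding of 21
structural/biochemical features, and combined Bayesian inference over the
resulting data partitions.

## Study-set data and screening

The packaged replicas of the study tables are TSV files under
`vrdphylo/data/`:

* `table1_polymerases.tsv` — 22 polymerase structures with taxonomy (family,
  genus, species, Baltimore class), PDB provenance (id, chain, resolution in
  Å) and co-crystallised molecules. Resolutions are stored with decimal
  commas, as in the source material; the parser accepts both commas and
  points and always serialises points. Note that the table's distinct genus
  labels number 16; `summarize_taxonomy` reports what the table contains.
* `table2_zscores.tsv` — the lower triangle of the pairwise structural
  similarity Z-score matrix (comma decimals). Z is the dimensionless
  similarity score of elastic structure comparison; pairs below Z = 2 are
  treated as incidental hits, and on the packaged matrix exactly one pair
  (JEV–HIV1, Z = 1.6) falls below that screen.
* `table3_characters.tsv` — the 22 × 21 matrix of unordered multistate
  characters (states 0–9, "N" = missing). Characters are *unordered*: any
  state may change to any other in a single step. The observed state-count
  profile is 13 binary, 7 ternary and 1 quaternary character.

Representative selection (`select_representatives`) retains at most two
structures per genus (four for *Enterovirus*), at most one per virus
species, ranked by: bound substrate/template first, then absence of
engineered mutations, then resolution (smaller is better), with the PDB id
as a deterministic tie-break. The source criteria list these preferences
without a precedence; the ranking order and tie-break are this package's
convention.

Greek taxon labels are transliterated (Φ6 → `Phi6`, Qβ → `Qbeta`) so that
every label is safe in NEXUS and Newick files; Table-header variants of
abbreviations are normalised to a single label set shared by all three
tables.

## Structural comparison

Structures are Cα traces (`StructureModel`), read from legacy PDB text by a
dedicated reader whose dialect rules are part of the contract: only Cα atoms
of the requested chain; the *first* altloc occurrence wins; insertion-coded
residues stay in file order; residue numbers are never rewritten.

* **Superposition** is the closed-form Kabsch solution (SVD of the
  cross-covariance). Reflections are explicitly rejected (determinant +1);
  a mirror image can never be returned because molecular chirality is
  physical. Collinear point sets are refused — the optimal rotation is not
  identifiable.
* **Correspondence** between two structures is the set of mutually-nearest
  Cα pairs within a cutoff (default 4.0 Å) after superposition, restricted
  to the longest subset that is strictly increasing in both sequences
  (longest increasing subsequence). This is a deterministic, testable
  stand-in for the correspondence an elastic alignment server would
  produce; it is *not* a reimplementation of such an algorithm.
* **Iterative refinement** alternates superposition and re-matching until
  the RMSD changes by less than 0.001 Å (at most 50 iterations). An
  iteration is accepted if it grows the correspondence, or keeps its size
  without increasing RMSD; this makes the RMSD trace non-increasing at
  stable correspondence size and guarantees termination.
* **Homomorphs** (hmG, hmF, hmA–hmE, and the helix-turn-helix thumb motif
  hmH) are user-supplied residue ranges. `homomorph_rmsd_table` computes
  the pairwise per-motif RMSD matrix used to argue that hmH is as
  structurally conserved as the similar-sized established motifs; pairs
  with unequal segment lengths are left missing rather than forced.
* **Secondary structure** is assigned by a purely geometric Cα classifier
  (in the spirit of P-SEA): residue *i* is classified from the distances
  |Cα_i−Cα_{i+2}|, |Cα_i−Cα_{i+3}|, |Cα_i−Cα_{i+4}| with windows centred on
  ideal helix (≈5.4, 5.1, 6.2 Å) and extended-strand (≥6.3, ≥8.5, ≥11 Å)
  geometry; everything else is loop, and the two residues at each terminus
  default to loop. A full hydrogen-bond (DSSP-style) assignment is out of
  scope because the package operates on Cα traces.
* **Core motif order**: the order of the hmA/hmB/hmC start residues
  classifies a polymerase core as canonical (A<B<C) or cyclically permuted
  (C<A<B, the birnaviral arrangement); any other or incomplete order is
  indeterminate.

## Structure-based multiple alignment and conservation

The multiple alignment is assembled progressively along a UPGMA guide tree
built from the dissimilarity d = max(Z) − Z (any monotone decreasing
transform would do; this one is fixed for determinism, with ties broken by
the lexicographically smallest pair of cluster representatives). Each merge
aligns two blocks through a residue correspondence between their
representative members, projected through the existing columns under the
"once a gap, always a gap" rule; every input residue appears in exactly one
column, so degapping any row reproduces its input sequence exactly.

Column conservation divides the count of the modal non-gap residue by the
*total* number of taxa — gaps dilute conservation. A column is flagged
"highly conserved" above 80% and "fully conserved" at exactly 100%. The
gap-inclusive denominator is this package's convention for gap-majority
columns and is the stricter reading of "conserved across the entire
alignment".

## Feature coding (characters A–U)

`char_coding` turns raw measurements into the 21 characters
deterministically. Thresholds follow the published feature descriptions;
where those leave a boundary unassigned, the package fixes it and documents
the choice in the module docstring:

* K (motif B helix length): "long" ⇔ ≥ 22 residues;
* N (motif C length): "short" ⇔ ≤ 10 residues;
* R (D–E connection): the second printed bound is treated as a typo;
  "long structured" ⇔ ≥ 20 residues;
* T (thumb size): "small" ⇔ ≤ 180 residues (strict ">180" reserved for
  large);
* M (B–C connection): ≥ 15 residues counts as "long helical" only with a
  helix of ≥ 8 residues inside, otherwise it codes as a loop;
* P state 0 is interpreted as a 3₁₀-helix followed by an α-helix.

Secondary-structure token strings are normalised to a four-letter alphabet
(a = α, b = β, g = 3₁₀, l = loop) before pattern matching; unmatched
patterns and absent measurements code as missing with a logged warning,
never as a guessed state.

The packaged per-taxon measurements
(`data/feature_measurements_synthetic.yaml`) are constructed stand-ins:
categorical facts (product, template, initiation, architecture, core order,
priming motif) follow the published matrix, while residue counts are
representative values consistent with the feature definitions, not numbers
measured from deposited coordinates. Encoding them reproduces the packaged
matrix cell for cell, which is the module's acceptance surface; the
round-trip property (every legal (feature, state) pair encodes back to
itself from `representative_measurement`) is tested exhaustively.

## Likelihood model

One reversible n-state core serves both partitions. A model is defined by
symmetric exchangeabilities and stationary frequencies; the rate matrix is
rescaled to one expected substitution per unit branch length. Transition
probabilities come from the symmetrised eigendecomposition (the similarity
transform by √π makes the matrix symmetric, so `eigh` applies).

Rate heterogeneity is the usual discretised gamma with four equal-weight
categories represented by their means, plus a proportion of invariant
sites. Convention: the mixture of the invariant class (rate 0) and the
scaled gamma categories has mean rate exactly 1, i.e. variable-class rates
are the mean-1 gamma means divided by (1 − p_inv). Branch lengths therefore
remain expected substitutions per site across the whole mixture.

Standard characters use the symmetric k-state Markov model, for which the
transition probability has the closed form
P(same) = 1/k + (k−1)/k·exp(−kt/(k−1)); the pruning kernel exploits this
(no matrix exponentials) and is vectorised across characters, with a numba
JIT when available and a pure-NumPy fallback that doubles as the reference
implementation in tests. By default characters are conditioned on being
variable (the Mkv correction, the MrBayes convention for standard data):
each character's likelihood is divided by 1 − k·L(constant), computed by
augmenting the site set with one all-constant pseudo-character per distinct
state count. A constant character under variable coding is a hard error
(probability-zero data). Missing states contribute flat partials.

No numerical rescaling is applied during pruning; with 64-bit floats this
is safe for the tree sizes targeted here (tens to a few hundred taxa) but
would underflow on trees of thousands of taxa.

## MCMC

The sampler mirrors the MrBayes run design: independent runs (default 2),
each with four chains — one cold, three incrementally heated with heat
1/(1 + 0.1·i) — one proposal per chain per generation and one state-swap
attempt per generation between a uniformly random chain pair. Samples are
cold-chain states recorded every 100 generations. Priors are MrBayes-style
defaults: uniform topology, exponential(10) branch lengths, exponential(1)
gamma shape, uniform(0,1) invariant fraction, flat Dirichlet simplices.

Proposals fall into two sets. Runs with a residue partition use classic
moves: a branch-length multiplier; stochastic nearest-neighbour
interchange (NNI); a symmetric subtree-exchange move (two non-nested
subtrees swap positions — an SPR-class rearrangement chosen over a
length-resampling SPR because its Hastings ratio is exactly 1); sliding
windows/multipliers for the gamma shape and invariant fraction; a
*correlated* joint move on (gamma shape, invariant fraction) that steps
along their well-known trade-off ridge (axis-aligned moves traverse that
ridge extremely slowly, which otherwise produces over-narrow, off-centre
posterior intervals at realistic chain lengths); and concentration-scaled
Dirichlet proposals for frequencies and exchangeabilities when those are
sampled.

Character-only (and prior-only) runs instead use *informed* topology
moves, affordable because the symmetric-Mk kernel is closed-form:

* **Gibbs NNI** — the three resolutions of a random internal edge are
  scored by their heated posterior and the new resolution is drawn from
  the exact conditional (acceptance is identically 1);
* **informed subtree reattachment** — a random subtree (leaf or clade) is
  pruned, a single inside/outside pass scores its reattachment at the
  midpoint of every edge of the reduced tree, the target edge is drawn
  from those weights, and the attachment point splits the target at a
  uniform fraction; the Hastings term combines the forward/reverse
  selection weights (identical by construction, since both are computed
  on the same reduced tree) with the edge-length Jacobian.

Weak discrete data leave the topology posterior broad, and naive
random-walk rearrangements then dominate the Monte-Carlo error of split
frequencies; the informed moves bring the integrated autocorrelation time
of split indicators close to one sampling interval.  Both are validated
against the exact prior (uniform topologies, exponential branch lengths;
Kolmogorov–Smirnov) and against direct re-pruning of every candidate
attachment.  Move weights are fixed in the engine.

Every run is a pure function of (configuration, seed): per-run generators
are spawned deterministically, and identical inputs give bit-identical
sample lists. A run may be started from a supplied tree (as MrBayes allows)
— parameter-recovery experiments start at the generating topology so that
they measure parameter estimation rather than topology search.

Desk-scale analyses in this package use 200,000 generations (the source
workflow used 10 million at 22 taxa); the scaled-down run length is the
package's default study condition, with the burn-in fraction (25%),
sampling stride (100) and heating unchanged.

Consensus trees are majority-rule over the pooled post-burn-in samples:
exactly the splits above 50% frequency (a tie between conflicting
resolutions keeps neither — a polytomy), supports are split frequencies,
and branch lengths are means over the samples containing the split.
Convergence between runs is summarised by the average standard deviation of
split frequencies (ASDSF): every split reaching 10% in at least one run
contributes the sample standard deviation (n−1 denominator) of its per-run
frequencies, and the report is the mean. Splits are bitmask sets over the
sorted taxon order, normalised to the side excluding the first taxon.

## Synthetic data

The generators provide ground truth for every stage:

* **Trees**: Yule (pure-birth) topologies via dendropy, run to the n-th
  birth and extended by one further exponential waiting time so terminal
  branches are strictly positive; expected total (unrooted) tree length is
  scale·(n−1)/birth rate, the Monte-Carlo oracle used in tests. Trees are
  unrooted (2n−3 branches).
* **Sequences**: root states from the stationary distribution, sites
  assigned to the invariant class with probability p_inv or to a gamma
  category otherwise, states evolved by exact transition probabilities
  down each branch; the per-site rates and invariant flags are recorded.
* **Characters**: the symmetric k-state process evolved by its closed
  form, with the packaged matrix's 13/7/1 state-count profile as default
  and optional rejection of constant characters.
* **Structures**: ideal helix geometry (1.5 Å rise, 100° twist, radius set
  so consecutive Cα distances are exactly 3.8 Å), near-straight strands,
  and self-avoiding random-walk loops, chained with a constant 3.8 Å step;
  `perturb_structure` applies a known rigid transform plus isotropic
  Gaussian noise and records the ground-truth transform.

One study seed fans out into named per-component substreams, so adding a
generator never changes another's output. What the generators deliberately
do *not* emulate: full-atom geometry, real secondary-structure
irregularity, structural divergence that correlates with sequence
divergence, cyclic-permutation evolution, and non-stationary or
covarion-like substitution processes. Tests passing on these fixtures
demonstrate correctness of the algorithms under their stated models, not
performance on real crystal structures.

## Problem sizes used in the test suite

The suite runs the full characters-only analysis at the desk-scale settings
above (22 taxa × 21 characters, 2 runs × 4 chains × 200k generations) and a
20-replicate parameter-recovery experiment (8 taxa, 5000 sites, gamma shape
0.5, invariant fraction 0.2, 12,000 generations per replicate, chains
started at the generating topology, coverage demanded in ≥ 90% of
replicates per parameter). Likelihood correctness is established against
exhaustive enumeration on ≤ 5-taxon, ≤ 4-state cases and closed forms
(Jukes–Cantor, two-taxon Mk/Mkv algebra).

## Known limitations

* The structure-based alignment of the original study exists only as
  figures, and the real coordinate sets require PDB downloads, so the
  alignment modules are exercised on synthetic and user-supplied
  structures; the packaged pipeline's quantitative surface is the tabular
  data and the character-matrix analysis.
* The Cα secondary-structure classifier is deliberately simple (three
  classes, distance windows); it is calibrated on ideal geometry and will
  under-call irregular helices in real structures.
* The sampler's proposal set is adequate for the data sizes above; very
  strong sequence partitions from a random starting tree can strand a
  single unheated chain on a local topology optimum (use multiple heated
  chains, or provide a start tree).
* ASDSF at 2,000 retained samples per run has an irreducible Monte-Carlo
  floor; values around 0.005–0.01 indicate agreement at sampling
  resolution, not exact run identity.
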