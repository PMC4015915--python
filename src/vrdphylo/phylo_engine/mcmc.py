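"""Metropolis-coupled MCMC over trees and substitution-model parameters.

The sampler follows the MrBayes design the study relied on: several
independent runs, each with one cold chain and a set of incrementally
heated chains (heat ``1/(1 + lambda * i)``), one proposal per chain per
generation, and one state-swap attempt between a random chain pair per
generation.  Partitions (protein alignment, standard characters) share the
topology and branch lengths; the standard partition uses the Mkv
variable-coding correction by default.

Priors mirror MrBayes defaults: uniform over unrooted topologies,
exponential(10) branch lengths, exponential(1) gamma shape, uniform(0,1)
proportion of invariant sites, flat Dirichlet on frequency and
exchangeability simplices.

Every run is a pure function of its seed: identical configuration and seed
reproduce the sample list bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import dirichlet as _dirichlet

from ..data_io import CharacterMatrix
from .likelihood import (
    CharacterData,
    MkSettings,
    mk_log_likelihood,
    mk_reattachment_log_likelihoods_fast,
    mk_subtree_inside,
    mkv_corrected_log_likelihood,
    _prune_generic,
    tip_partials,
)
from .substitution import RateHeterogeneity, SubstitutionModel
from .tree import Tree


@dataclass(frozen=True)
class MCMCConfig:
    n_generations: int = 200_000
    sample_every: int = 100
    n_runs: int = 2
    n_chains: int = 4  # 1 cold + heated
    heating_lambda: float = 0.1
    burn_in_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.n_chains < 1 or self.n_runs < 1:
            raise ValueError("need at least one chain and one run")

    def heat(self, i: int) -> float:
        return 1.0 / (1.0 + self.heating_lambda * i)


@dataclass(frozen=True)
class PriorSettings:
    branch_length_rate: float = 10.0  # exponential prior on each branch
    alpha_rate: float = 1.0  # exponential prior on the gamma shape


@dataclass(frozen=True)
class SequencePartition:
    """Aligned residue data plus its substitution model configuration."""

    data: Mapping[str, str]
    model: SubstitutionModel
    heterogeneity: RateHeterogeneity | None = None
    sample_alpha: bool = True
    sample_p_inv: bool = True
    sample_frequencies: bool = False
    sample_exchangeabilities: bool = False


@dataclass(frozen=True)
class CharacterPartition:
    matrix: CharacterMatrix
    settings: MkSettings = field(default_factory=MkSettings)


@dataclass
class PosteriorSample:
    """Sampled cold-chain states of one run."""

    taxa: tuple[str, ...]
    generations: list[int] = field(default_factory=list)
    trees: list[Tree] = field(default_factory=list)
    params: list[dict] = field(default_factory=list)
    log_posteriors: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.generations)

    def post_burn_in(self, burn_in_fraction: float) -> "PosteriorSample":
        cut = int(math.floor(len(self) * burn_in_fraction))
        return PosteriorSample(
            self.taxa,
            self.generations[cut:],
            self.trees[cut:],
            self.params[cut:],
            self.log_posteriors[cut:],
        )

    def trace_frame(self):
        import pandas as pd

        rows = [
            {"generation": g, "log_posterior": lp, **p}
            for g, lp, p in zip(self.generations, self.log_posteriors, self.params)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chain state


class _ChainState:
    __slots__ = ("tree", "alpha", "p_inv", "freqs", "exch", "model",
                 "ln_like", "ln_prior")

    def __init__(self, tree, alpha, p_inv, freqs, exch, model):
        self.tree = tree
        self.alpha = alpha
        self.p_inv = p_inv
        self.freqs = freqs
        self.exch = exch
        self.model = model
        self.ln_like = -math.inf
        self.ln_prior = -math.inf

    @property
    def ln_posterior(self) -> float:
        return self.ln_like + self.ln_prior


class _Engine:
    """One run: data, priors, proposals and the generation loop."""

    def __init__(self, seq: SequencePartition | None,
                 chars: CharacterPartition | None,
                 cfg: MCMCConfig, priors: PriorSettings,
                 rng: np.random.Generator,
                 taxa: Sequence[str] | None = None,
                 start_tree: Tree | None = None):
        if seq is None and chars is None and taxa is None:
            raise ValueError("a data partition (or explicit taxa for "
                             "prior-only sampling) is required")
        self.cfg = cfg
        self.priors = priors
        self.rng = rng
        self.seq = seq
        taxa = set(taxa or ())
        if seq is not None:
            taxa |= set(seq.data)
        if chars is not None:
            taxa |= set(chars.matrix.taxa)
        self.taxa = tuple(sorted(taxa))
        if chars is not None:
            matrix = chars.matrix
            if tuple(sorted(matrix.taxa)) != self.taxa:
                raise ValueError("partitions must cover the same taxa")
            reordered = CharacterMatrix(
                self.taxa, matrix.characters,
                tuple(matrix.row(t) for t in self.taxa),
            )
            self.char_data = CharacterData.from_matrix(reordered, chars.settings)
            self.variable_coding = chars.settings.variable_coding
        else:
            self.char_data = None
        if seq is not None:
            if set(seq.data) != set(self.taxa):
                raise ValueError("partitions must cover the same taxa")
            self.partials, self.counts = tip_partials(
                self.taxa, seq.data, seq.model.alphabet
            )
            # invariant-class pattern compatibility, fixed across the run
            self._tip_product = np.prod(self.partials, axis=0)
        if start_tree is not None and tuple(start_tree.taxa) != self.taxa:
            raise ValueError("start tree taxa must match the data taxa "
                             "(sorted order)")
        self.start_tree = start_tree
        n = len(self.taxa)
        root = start_tree.root if start_tree is not None else n
        self._edge_ids = [v for v in range(2 * n - 2) if v != root]
        self._internal_ids = [v for v in range(n, 2 * n - 2) if v != root]
        self.moves = self._build_moves()

    # -- likelihood and prior ---------------------------------------------

    def _seq_lnl(self, state: _ChainState) -> float:
        het = None
        if self.seq.heterogeneity is not None:
            het = RateHeterogeneity(
                gamma_shape=state.alpha,
                n_categories=self.seq.heterogeneity.n_categories,
                p_invariant=state.p_inv,
            )
        if het is None:
            rates, weights = np.ones(1), np.ones(1)
            p_inv = 0.0
        else:
            rates, weights = het.mixture_rates()
            p_inv = het.p_invariant
        cat = _prune_generic(state.tree, self.partials, state.model, rates)
        site = weights @ cat
        if p_inv > 0:
            pi = state.model.stationary_frequencies
            site = site + p_inv * (pi @ self._tip_product)
        with np.errstate(divide="ignore"):
            return float(np.dot(self.counts, np.log(site)))

    def log_likelihood(self, state: _ChainState) -> float:
        total = 0.0
        if self.char_data is not None:
            if self.variable_coding:
                total += mkv_corrected_log_likelihood(state.tree, self.char_data)
            else:
                total += mk_log_likelihood(state.tree, self.char_data)
        if self.seq is not None:
            total += self._seq_lnl(state)
        return total

    def log_prior(self, state: _ChainState) -> float:
        # blen[root] is pinned to 0, so summing the whole array is safe
        lam = self.priors.branch_length_rate
        n_edges = state.tree.n_nodes - 1
        lp = n_edges * math.log(lam) - lam * float(state.tree.blen.sum())
        if self.seq is not None and self.seq.heterogeneity is not None:
            ar = self.priors.alpha_rate
            lp += math.log(ar) - ar * state.alpha  # exponential on alpha
            # p_inv: uniform(0, 1) - constant
        # Dirichlet(1) simplices and uniform topology: constant
        return lp

    def refresh(self, state: _ChainState) -> None:
        state.ln_like = self.log_likelihood(state)
        state.ln_prior = self.log_prior(state)

    # -- initial states ----------------------------------------------------

    def initial_state(self) -> _ChainState:
        if self.start_tree is not None:
            tree = self.start_tree.copy()
        else:
            n_nodes = 2 * len(self.taxa) - 2
            blens = self.rng.exponential(1.0 / self.priors.branch_length_rate,
                                         size=n_nodes)
            tree = Tree.random_topology(self.taxa, self.rng,
                                        branch_lengths=blens)
        if self.seq is not None:
            het = self.seq.heterogeneity
            alpha = het.gamma_shape if het else 1.0
            p_inv = het.p_invariant if het else 0.0
            model = self.seq.model
            freqs = model.stationary_frequencies.copy()
            iu = np.triu_indices(model.n_states, 1)
            exch = model.exchangeabilities[iu].copy()
        else:
            alpha, p_inv, model, freqs, exch = 1.0, 0.0, None, None, None
        state = _ChainState(tree, alpha, p_inv, freqs, exch, model)
        self.refresh(state)
        return state

    # -- proposals ---------------------------------------------------------

    def _move_blen(self, state: _ChainState, beta: float):
        tree = state.tree
        edges = self._edge_ids
        v = edges[int(self.rng.integers(len(edges)))]
        old = tree.blen[v]
        m = math.exp(1.0 * (self.rng.random() - 0.5))
        tree.blen[v] = old * m

        def undo():
            tree.blen[v] = old

        return math.log(m), undo

    @staticmethod
    def _swap_positions(tree: Tree, a: int, b: int) -> None:
        pa, pb = int(tree.parent[a]), int(tree.parent[b])
        tree.children[pa][tree.children[pa].index(a)] = b
        tree.children[pb][tree.children[pb].index(b)] = a
        tree.parent[a], tree.parent[b] = pb, pa
        tree.invalidate()

    def _move_nni(self, state: _ChainState, beta: float):
        tree = state.tree
        internal = self._internal_ids
        if not internal:
            return None
        v = internal[int(self.rng.integers(len(internal)))]
        u = int(tree.parent[v])
        a = tree.children[v][int(self.rng.integers(len(tree.children[v])))]
        others = [c for c in tree.children[u] if c != v]
        b = others[int(self.rng.integers(len(others)))]
        self._swap_positions(tree, a, b)

        def undo():
            self._swap_positions(tree, a, b)

        return 0.0, undo


    def _move_nni_gibbs(self, state: _ChainState, beta: float):
        """Gibbs-style nearest-neighbour interchange.

        The three resolutions of a random internal edge are scored by their
        (heated) posterior and the new resolution is drawn from the exact
        conditional distribution; the Hastings term makes the Metropolis
        acceptance exactly 1.  Branch lengths travel with their subtrees,
        so the prior is unchanged and only likelihoods matter.
        """
        tree = state.tree
        internal = self._internal_ids
        if not internal:
            return None
        v = internal[int(self.rng.integers(len(internal)))]
        u = int(tree.parent[v])
        a1, a2 = tree.children[v]
        others = [c for c in tree.children[u] if c != v]
        b = others[int(self.rng.integers(len(others)))]
        lnls = [state.ln_like]
        for a in (a1, a2):
            self._swap_positions(tree, a, b)
            lnls.append(self.log_likelihood(state))
            self._swap_positions(tree, a, b)
        arr = np.array(lnls)
        w = np.exp(beta * (arr - arr.max()))
        w /= w.sum()
        j = int(np.searchsorted(np.cumsum(w), self.rng.random()))
        if j == 0:
            return None  # resampled the current resolution
        a = (a1, a2)[j - 1]
        self._swap_positions(tree, a, b)

        def undo():
            self._swap_positions(tree, a, b)

        return beta * (lnls[0] - lnls[j]), undo

    def _move_subtree_reattach(self, state: _ChainState, beta: float):
        """Informed subtree reattachment (an SPR-class move).

        A random subtree (a leaf or a whole clade) is pruned, every edge
        of the reduced tree is scored by the (heated) likelihood of
        reattaching the subtree at its midpoint, and the target edge is
        drawn from those weights; the final attachment point splits the
        target edge at a uniform fraction.  The Hastings term combines the
        forward/reverse selection weights (computed on the identical
        reduced tree) with the edge-length Jacobian L_target / L_origin.
        Subtrees hanging directly off the root node are skipped (other
        moves relocate them).
        """
        tree = state.tree
        x = self._edge_ids[int(self.rng.integers(len(self._edge_ids)))]
        p = int(tree.parent[x])
        if p == tree.root:
            return None
        g = int(tree.parent[p])
        s = [c for c in tree.children[p] if c != x][0]
        lp, ls = tree.blen[p], tree.blen[s]
        orig_children = list(tree.children[p])
        l_origin = lp + ls
        # prune x (node p floats, keeping its id)
        tree.children[g][tree.children[g].index(p)] = s
        tree.parent[s] = g
        tree.blen[s] = l_origin
        tree.invalidate()

        def attach(e: int, upper: float, lower: float) -> None:
            pe = int(tree.parent[e])
            tree.children[pe][tree.children[pe].index(e)] = p
            tree.parent[p] = pe
            tree.children[p] = [e, x]
            tree.parent[e] = p
            tree.parent[x] = p
            tree.blen[p] = upper
            tree.blen[e] = lower
            tree.invalidate()

        def detach(e: int, restore: float) -> None:
            pe = int(tree.parent[p])
            tree.children[pe][tree.children[pe].index(p)] = e
            tree.parent[e] = pe
            tree.blen[e] = restore
            tree.invalidate()

        # every edge of the reduced tree is a valid target (this excludes
        # x's own subtree, which is no longer reachable from the root)
        candidates = [int(v) for v in tree.postorder() if v != tree.root]
        if self.seq is None and self.char_data is not None:
            # characters only: score all attachments from one
            # inside/outside pass instead of re-pruning per candidate
            pendant = mk_subtree_inside(tree, self.char_data, x)
            lnls = mk_reattachment_log_likelihoods_fast(
                tree, self.char_data, pendant, candidates, tree.blen[x])
        else:
            lnls = np.empty(len(candidates))
            for idx, e in enumerate(candidates):
                full = tree.blen[e]
                attach(e, full / 2.0, full / 2.0)
                lnls[idx] = self.log_likelihood(state)
                detach(e, full)
        w = np.exp(beta * (lnls - lnls.max()))
        w /= w.sum()
        j = int(np.searchsorted(np.cumsum(w), self.rng.random()))
        e = candidates[j]
        i = candidates.index(s)
        l_target = tree.blen[e]
        u = self.rng.random()
        attach(e, u * l_target, (1.0 - u) * l_target)
        log_hastings = (math.log(w[i]) - math.log(w[j])
                        + math.log(l_target) - math.log(l_origin))

        def undo():
            detach(e, l_target)
            # restore the original attachment exactly
            pe = int(tree.parent[s])
            tree.children[pe][tree.children[pe].index(s)] = p
            tree.parent[p] = pe
            tree.children[p] = orig_children
            tree.parent[s] = p
            tree.parent[x] = p
            tree.blen[p] = lp
            tree.blen[s] = ls
            tree.invalidate()

        return log_hastings, undo

    def _move_subtree_swap(self, state: _ChainState, beta: float):
        tree = state.tree
        nodes = self._edge_ids
        for _ in range(10):
            x = nodes[int(self.rng.integers(len(nodes)))]
            y = nodes[int(self.rng.integers(len(nodes)))]
            if x == y:
                continue
            if tree.parent[x] == tree.parent[y]:
                continue
            if tree.is_ancestor(x, y) or tree.is_ancestor(y, x):
                continue
            self._swap_positions(tree, x, y)

            def undo():
                self._swap_positions(tree, x, y)

            return 0.0, undo
        return None

    def _move_alpha(self, state: _ChainState, beta: float):
        old = state.alpha
        m = math.exp(0.7 * (self.rng.random() - 0.5))
        state.alpha = old * m

        def undo():
            state.alpha = old

        return math.log(m), undo

    def _move_p_inv(self, state: _ChainState, beta: float):
        old = state.p_inv
        x = old + 0.2 * (self.rng.random() - 0.5)
        # reflect into [0, 1)
        x = abs(x)
        if x >= 1.0:
            x = 2.0 - x - 1e-12
        state.p_inv = x

        def undo():
            state.p_inv = old

        return 0.0, undo

    def _move_alpha_pinv_joint(self, state: _ChainState, beta: float):
        """Correlated update along the gamma-shape / invariant-fraction
        ridge: the two parameters trade off strongly, so axis-aligned
        moves alone traverse the posterior very slowly."""
        old_a, old_p = state.alpha, state.p_inv
        delta = 0.3 * (self.rng.random() - 0.5)
        new_p = old_p + delta
        if not 0.0 <= new_p < 1.0:
            return None  # outside support: counts as a rejected proposal
        log_m = 2.5 * delta
        state.p_inv = new_p
        state.alpha = old_a * math.exp(log_m)

        def undo():
            state.alpha, state.p_inv = old_a, old_p

        # Jacobian of the deterministic alpha scaling
        return log_m, undo

    def _propose_simplex(self, current: np.ndarray, conc: float):
        cur = np.clip(current, 1e-8, None)
        cur = cur / cur.sum()
        prop = self.rng.dirichlet(conc * cur)
        prop = np.clip(prop, 1e-8, None)
        prop = prop / prop.sum()
        fwd = _dirichlet.logpdf(prop, conc * cur)
        rev = _dirichlet.logpdf(cur, conc * prop)
        return prop, rev - fwd

    def _rebuild_model(self, state: _ChainState) -> None:
        n = state.model.n_states
        full = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        full[iu] = state.exch
        full += full.T
        state.model = SubstitutionModel(n, full, state.freqs,
                                        alphabet=state.model.alphabet)

    def _move_freqs(self, state: _ChainState, beta: float):
        old_freqs, old_model = state.freqs, state.model
        prop, lh = self._propose_simplex(old_freqs, 300.0)
        state.freqs = prop
        self._rebuild_model(state)

        def undo():
            state.freqs, state.model = old_freqs, old_model

        return lh, undo

    def _move_exch(self, state: _ChainState, beta: float):
        old_exch, old_model = state.exch, state.model
        prop, lh = self._propose_simplex(old_exch / old_exch.sum(), 100.0)
        state.exch = prop * prop.size  # keep a convenient scale; Q rescaled anyway
        self._rebuild_model(state)

        def undo():
            state.exch, state.model = old_exch, old_model

        return lh, undo

    def _build_moves(self):
        if self.seq is None:
            # character-only (or prior-only) runs afford informed topology
            # moves: the closed-form Mk kernel makes Gibbs NNI and scored
            # leaf reattachment cheap, and they mix far better than naive
            # rearrangements on weak data
            moves = [(self._move_blen, 2.0), (self._move_nni_gibbs, 3.0),
                     (self._move_subtree_swap, 0.5),
                     (self._move_subtree_reattach, 5.0)]
            funcs, weights = zip(*moves)
            cum = np.cumsum(np.array(weights) / sum(weights))
            return funcs, cum
        moves = [(self._move_blen, 5.0), (self._move_nni, 4.0),
                 (self._move_subtree_swap, 1.0)]
        if self.seq is not None and self.seq.heterogeneity is not None:
            if self.seq.sample_alpha:
                moves.append((self._move_alpha, 1.5))
            if self.seq.sample_p_inv:
                moves.append((self._move_p_inv, 1.5))
            if self.seq.sample_alpha and self.seq.sample_p_inv:
                moves.append((self._move_alpha_pinv_joint, 1.5))
        if self.seq is not None and self.seq.sample_frequencies:
            moves.append((self._move_freqs, 1.0))
        if self.seq is not None and self.seq.sample_exchangeabilities:
            moves.append((self._move_exch, 1.0))
        funcs, weights = zip(*moves)
        cum = np.cumsum(np.array(weights) / sum(weights))
        return funcs, cum

    # -- generation loop ---------------------------------------------------

    def run(self) -> PosteriorSample:
        cfg = self.cfg
        chains = [self.initial_state() for _ in range(cfg.n_chains)]
        sample = PosteriorSample(self.taxa)
        funcs, cum = self.moves
        heats = [cfg.heat(i) for i in range(cfg.n_chains)]
        for gen in range(1, cfg.n_generations + 1):
            for ci, state in enumerate(chains):
                beta = heats[ci]
                mv = funcs[int(np.searchsorted(cum, self.rng.random()))]
                proposal = mv(state, beta)
                if proposal is None:
                    continue
                log_hastings, undo = proposal
                old_like, old_prior = state.ln_like, state.ln_prior
                new_like = self.log_likelihood(state)
                new_prior = self.log_prior(state)
                log_acc = beta * ((new_like + new_prior)
                                  - (old_like + old_prior)) + log_hastings
                if math.log(self.rng.random() + 1e-300) < log_acc:
                    state.ln_like, state.ln_prior = new_like, new_prior
                else:
                    undo()
                    state.tree.invalidate()
            if cfg.n_chains > 1:
                i = int(self.rng.integers(cfg.n_chains))
                j = int(self.rng.integers(cfg.n_chains - 1))
                if j >= i:
                    j += 1
                bi, bj = heats[i], heats[j]
                delta = (bi - bj) * (chains[j].ln_posterior
                                     - chains[i].ln_posterior)
                if math.log(self.rng.random() + 1e-300) < delta:
                    chains[i], chains[j] = chains[j], chains[i]
            if gen % cfg.sample_every == 0:
                cold = chains[0]
                sample.generations.append(gen)
                sample.trees.append(cold.tree.copy())
                p = {"tree_length": cold.tree.total_length,
                     "log_likelihood": cold.ln_like}
                if self.seq is not None and self.seq.heterogeneity is not None:
                    p["alpha"] = cold.alpha
                    p["p_inv"] = cold.p_inv
                sample.params.append(p)
                sample.log_posteriors.append(cold.ln_posterior)
        return sample


def mcmc_run(
    sequence_partition: SequencePartition | None = None,
    character_partition: CharacterPartition | None = None,
    cfg: MCMCConfig | None = None,
    priors: PriorSettings | None = None,
    taxa: Sequence[str] | None = None,
    start_tree: Tree | None = None,
) -> list[PosteriorSample]:
    """Run ``cfg.n_runs`` independent Metropolis-coupled analyses.

    Returns one :class:`PosteriorSample` per run.  Runs differ only in
    their random substream; all are derived deterministically from
    ``cfg.seed``.  With no data partition (``taxa`` given explicitly) the
    sampler explores the prior.
    """
    cfg = cfg or MCMCConfig()
    priors = priors or PriorSettings()
    out = []
    for run_idx in range(cfg.n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(run_idx,))
        )
        engine = _Engine(sequence_partition, character_partition, cfg,
                         priors, rng, taxa=taxa, start_tree=start_tree)
        out.append(engine.run())
    return out
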