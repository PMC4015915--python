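"""Consensus trees, clade supports and split-frequency diagnostics.

Splits are represented as bitmasks over the canonical (sorted) taxon order,
normalised to the side not containing the first taxon.  The majority-rule
consensus keeps exactly the splits appearing in more than half of the
pooled post-burn-in trees (a tie between two conflicting resolutions keeps
neither, producing a polytomy); supports are split frequencies and branch
lengths are means over the samples containing the split.

Convergence between independent runs is summarised by the average standard
deviation of split frequencies (ASDSF): for every split reaching a minimum
frequency in at least one run, the sample standard deviation of its
frequencies across runs, averaged over the included splits.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .mcmc import PosteriorSample
from .tree import Tree


def split_frequencies(
    samples: PosteriorSample, burn_in_fraction: float = 0.0
) -> dict[int, float]:
    """Frequency of every non-trivial split among the post-burn-in trees."""
    kept = samples.post_burn_in(burn_in_fraction)
    if not len(kept):
        raise ValueError("no post-burn-in samples")
    counts: dict[int, int] = defaultdict(int)
    for tree in kept.trees:
        for mask in tree.splits():
            counts[mask] += 1
    n = len(kept)
    return {mask: c / n for mask, c in counts.items()}


@dataclass(frozen=True)
class ConsensusTree:
    """Majority-rule consensus with posterior supports."""

    taxa: tuple[str, ...]
    splits: Mapping[int, float]  # mask -> support (> 0.5)
    split_lengths: Mapping[int, float]  # mask -> mean branch length
    leaf_lengths: tuple[float, ...]

    def taxon_mask(self, taxa: Sequence[str]) -> int:
        mask = 0
        for t in taxa:
            mask |= 1 << self.taxa.index(t)
        return mask

    def _normalise(self, mask: int) -> int:
        full = (1 << len(self.taxa)) - 1
        return (full ^ mask) if (mask & 1) else mask

    def to_newick(self) -> str:
        """Newick with supports as internal-node labels (polytomies kept)."""
        n = len(self.taxa)
        items: dict[int, str] = {}
        masks = sorted(self.splits, key=lambda m: bin(m).count("1"))
        pending = {(1 << i): f"{self.taxa[i]}:{self.leaf_lengths[i]:.10g}"
                   for i in range(n)}
        # Note: every retained split is compatible with all others, so a
        # smallest-first greedy assembly is well defined.
        full = (1 << n) - 1
        cover = dict(pending)
        for m in masks:
            inside = [k for k in cover if k & m == k]
            label = ",".join(cover[k] for k in sorted(inside))
            sup = self.splits[m]
            ln = self.split_lengths[m]
            for k in inside:
                del cover[k]
            cover[m] = f"({label}){sup:.4f}:{ln:.10g}"
        rest = ",".join(cover[k] for k in sorted(cover))
        return f"({rest});"

    def to_dendropy(self):
        import dendropy

        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True)


def majority_consensus(
    samples: Sequence[PosteriorSample], burn_in_fraction: float = 0.25
) -> ConsensusTree:
    """Majority-rule consensus over the pooled post-burn-in samples."""
    kept = [s.post_burn_in(burn_in_fraction) for s in samples]
    total = sum(len(k) for k in kept)
    if total == 0:
        raise ValueError("no post-burn-in samples")
    taxa = kept[0].taxa
    counts: dict[int, int] = defaultdict(int)
    length_sums: dict[int, float] = defaultdict(float)
    n_leaves = len(taxa)
    leaf_sums = np.zeros(n_leaves)
    for k in kept:
        if k.taxa != taxa:
            raise ValueError("runs cover different taxa")
        for tree in k.trees:
            for mask, blen in tree.splits(with_lengths=True).items():
                counts[mask] += 1
                length_sums[mask] += blen
            leaf_sums += tree.leaf_lengths()
    splits = {}
    lengths = {}
    for mask, c in counts.items():
        freq = c / total
        if freq > 0.5:
            splits[mask] = freq
            lengths[mask] = length_sums[mask] / c
    return ConsensusTree(taxa, splits, lengths,
                         tuple(leaf_sums / total))


def clade_support(
    c: ConsensusTree, taxa: Sequence[str]
) -> tuple[bool, float | None]:
    """Is the taxon set a clade of the consensus, and with what support?

    Trivial groups (singletons, the full set, or all-but-one) are
    monophyletic by definition and carry no support value.
    """
    for t in taxa:
        if t not in c.taxa:
            raise KeyError(f"unknown taxon {t!r}")
    mask = c._normalise(c.taxon_mask(taxa))
    size = bin(mask).count("1")
    if size < 2 or size > len(c.taxa) - 2:
        return True, None
    if mask in c.splits:
        return True, c.splits[mask]
    return False, None


def never_separated(c: ConsensusTree, taxa: Sequence[str]) -> bool:
    """True if no retained split places part of ``taxa`` on each side."""
    mask = c.taxon_mask(taxa)
    full = (1 << len(c.taxa)) - 1
    for m in c.splits:
        if (m & mask) and ((full ^ m) & mask):
            return False
    return True


@dataclass(frozen=True)
class ConvergenceReport:
    asdsf: float
    per_split: Mapping[int, tuple[float, ...]]  # mask -> per-run frequencies
    n_splits: int


def asdsf(
    run_samples: Sequence[PosteriorSample],
    burn_in_fraction: float = 0.25,
    min_frequency: float = 0.1,
) -> ConvergenceReport:
    """Average standard deviation of split frequencies across runs.

    A split enters the average when it reaches ``min_frequency`` in at
    least one run; its contribution is the sample standard deviation
    (n-1 denominator) of its per-run frequencies.
    """
    if len(run_samples) < 2:
        raise ValueError("at least two runs required")
    freqs = [split_frequencies(s, burn_in_fraction) for s in run_samples]
    included = set()
    for f in freqs:
        included |= {m for m, v in f.items() if v >= min_frequency}
    if not included:
        return ConvergenceReport(0.0, {}, 0)
    per_split = {}
    sds = []
    for m in sorted(included):
        values = tuple(f.get(m, 0.0) for f in freqs)
        per_split[m] = values
        sds.append(float(np.std(values, ddof=1)))
    return ConvergenceReport(float(np.mean(sds)), per_split, len(sds))
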