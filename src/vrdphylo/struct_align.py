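"""Progressive structure-based multiple sequence alignment and conservation.

Pairwise residue correspondences obtained from rigid superposition are merged
into a multiple alignment along a UPGMA guide tree built from structural
dissimilarities (``max Z − Z`` of the pairwise Z-score matrix).  Per-column
conservation statistics reproduce the annotation conventions of the study's
alignment figures: a position is "highly conserved" when the modal non-gap
residue exceeds 80% of all taxa (gaps dilute conservation) and "fully
conserved" at 100%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .struct_compare import (
    ResidueCorrespondence,
    StructureError,
    StructureModel,
    iterative_superpose,
)


@dataclass(frozen=True)
class GuideNode:
    """A node of the (rooted, binary) progressive-merge order."""

    height: float
    label: str | None = None
    left: "GuideNode | None" = None
    right: "GuideNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        return self.left.leaves() + self.right.leaves()

    def representative(self) -> str:
        """Lexicographically smallest member label (deterministic anchor)."""
        return min(self.leaves())


@dataclass(frozen=True)
class GuideTree:
    root: GuideNode

    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves()

    def merges(self) -> list[GuideNode]:
        """Internal nodes in merge (height, then construction) order."""
        out: list[GuideNode] = []

        def walk(node: GuideNode) -> None:
            if node.is_leaf:
                return
            walk(node.left)
            walk(node.right)
            out.append(node)

        walk(self.root)
        out.sort(key=lambda n: n.height)
        return out


def build_guide_tree(d: pd.DataFrame) -> GuideTree:
    """UPGMA agglomeration of a symmetric dissimilarity matrix.

    Ties are broken by the lexicographically smallest pair of cluster
    representatives, making the merge order deterministic.
    """
    labels = list(d.index)
    if len(labels) < 2:
        raise ValueError("at least 2 labels required")
    mat = d.to_numpy(dtype=float)
    if mat.shape != (len(labels), len(labels)) or not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if (mat < 0).any() or not np.allclose(np.diag(mat), 0):
        raise ValueError("dissimilarities must be non-negative with zero diagonal")

    clusters: dict[int, GuideNode] = {
        i: GuideNode(0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in clusters}
    dist = {
        frozenset((i, j)): mat[i, j]
        for i in clusters
        for j in clusters
        if i < j
    }
    next_id = len(labels)
    while len(clusters) > 1:
        def key(pair):
            i, j = sorted(pair)
            reps = sorted((clusters[i].representative(), clusters[j].representative()))
            return (dist[pair], reps[0], reps[1])

        best = min(dist, key=key)
        i, j = sorted(best)
        h = dist[best]
        merged = GuideNode(h, left=clusters[i], right=clusters[j])
        ni, nj = sizes[i], sizes[j]
        del clusters[i], clusters[j]
        new_dist = {}
        for k in clusters:
            new_dist[k] = (
                ni * dist[frozenset((i, k))] + nj * dist[frozenset((j, k))]
            ) / (ni + nj)
        dist = {
            p: v for p, v in dist.items() if i not in p and j not in p
        }
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        for k, v in new_dist.items():
            dist[frozenset((next_id, k))] = v
        next_id += 1
    return GuideTree(next(iter(clusters.values())))


def zscores_to_dissimilarity(z) -> pd.DataFrame:
    """Convert a Z-score matrix to dissimilarities d = max(Z) − Z."""
    df = z.to_frame()
    d = z.max_z - df
    np.fill_diagonal(d.values, 0.0)
    return d


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over the amino-acid alphabet plus '-'."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows) or not self.rows:
            raise ValueError("one row per taxon required")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{r}\n" for t, r in zip(self.taxa, self.rows))


def _merge_blocks(
    block_a: dict[str, list[int | None]],
    block_b: dict[str, list[int | None]],
    rep_a: str,
    rep_b: str,
    corr: ResidueCorrespondence,
) -> dict[str, list[int | None]]:
    """Merge two alignment blocks given a correspondence between their
    representative sequences ("once a gap, always a gap")."""
    row_a, row_b = block_a[rep_a], block_b[rep_b]
    col_of_a = {res: c for c, res in enumerate(row_a) if res is not None}
    col_of_b = {res: c for c, res in enumerate(row_b) if res is not None}
    matched: list[tuple[int, int]] = []
    for i, j in corr.pairs:
        if i not in col_of_a or j not in col_of_b:
            raise StructureError(
                f"correspondence refers to residue missing from block ({i}, {j})"
            )
        matched.append((col_of_a[i], col_of_b[j]))
    # correspondence is increasing in residues, hence in columns too
    na = len(row_a)
    nb = len(row_b)
    order: list[tuple[int | None, int | None]] = []
    pa = pb = 0
    for ca, cb in matched + [(na, nb)]:
        while pa < ca:
            order.append((pa, None))
            pa += 1
        while pb < cb:
            order.append((None, pb))
            pb += 1
        if ca < na:
            order.append((ca, cb))
            pa, pb = ca + 1, cb + 1
    merged: dict[str, list[int | None]] = {}
    for label, row in block_a.items():
        merged[label] = [row[ca] if ca is not None else None for ca, _ in order]
    for label, row in block_b.items():
        merged[label] = [row[cb] if cb is not None else None for _, cb in order]
    return merged


def merge_correspondences(
    sequences: Mapping[str, str],
    pairwise: Mapping[tuple[str, str], ResidueCorrespondence],
    guide: GuideTree,
) -> MultipleAlignment:
    """Progressively merge sequences into a multiple alignment.

    ``pairwise`` supplies, for every guide-tree merge, a residue
    correspondence between the representative (lexicographically smallest)
    members of the two blocks, keyed by the ordered label pair.  Every input
    residue appears in exactly one column of the result.
    """
    blocks: dict[str, dict[str, list[int | None]]] = {
        lab: {lab: list(range(len(seq)))} for lab, seq in sequences.items()
    }

    def lookup(a: str, b: str) -> ResidueCorrespondence:
        if (a, b) in pairwise:
            return pairwise[(a, b)]
        if (b, a) in pairwise:
            flipped = tuple((j, i) for i, j in pairwise[(b, a)].pairs)
            return ResidueCorrespondence(flipped)
        raise KeyError(f"no correspondence for merge ({a}, {b})")

    def walk(node: GuideNode) -> dict[str, list[int | None]]:
        if node.is_leaf:
            return blocks[node.label]
        left = walk(node.left)
        right = walk(node.right)
        rep_l = min(left)
        rep_r = min(right)
        return _merge_blocks(left, right, rep_l, rep_r, lookup(rep_l, rep_r))

    final = walk(guide.root)
    taxa = tuple(guide.leaves())
    rows = []
    for t in taxa:
        seq = sequences[t]
        rows.append(
            "".join("-" if r is None else seq[r] for r in final[t])
        )
    return MultipleAlignment(taxa, tuple(rows))


def align_structures(
    structs: Sequence[StructureModel],
    guide: GuideTree | None = None,
    cutoff: float = 4.0,
) -> MultipleAlignment:
    """Convenience pipeline: superpose structures pairwise and merge.

    Pairwise correspondences between merge representatives come from
    iterative superposition seeded with the leading-residue identity map.
    Without a guide tree, structures are merged in label order.
    """
    by_label = {s.label: s for s in structs}
    if guide is None:
        labels = sorted(by_label)
        node = GuideNode(0.0, label=labels[0])
        for i, lab in enumerate(labels[1:], start=1):
            node = GuideNode(float(i), left=node, right=GuideNode(0.0, label=lab))
        guide = GuideTree(node)

    pairwise: dict[tuple[str, str], ResidueCorrespondence] = {}

    def corr_for(la: str, lb: str) -> ResidueCorrespondence:
        a, b = by_label[la], by_label[lb]
        n = min(len(a), len(b))
        seed = ResidueCorrespondence(tuple((i, i) for i in range(n)))
        _, corr = iterative_superpose(a, b, seed, cutoff=cutoff)
        return corr

    def walk(node: GuideNode) -> None:
        if node.is_leaf:
            return
        walk(node.left)
        walk(node.right)
        rep_l, rep_r = node.left.representative(), node.right.representative()
        key = tuple(sorted((rep_l, rep_r)))
        if key not in pairwise:
            pairwise[key] = corr_for(*key)

    walk(guide.root)
    sequences = {s.label: s.sequence for s in structs}
    return merge_correspondences(sequences, pairwise, guide)


# ---------------------------------------------------------------------------
# conservation


@dataclass(frozen=True)
class ColumnStats:
    """Per-column residue frequencies and conservation flags."""

    frequencies: tuple[Mapping[str, int], ...]  # gap-inclusive
    consensus: str
    fraction: tuple[float, ...]
    conserved80: tuple[bool, ...]
    conserved100: tuple[bool, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(1, len(self.consensus) + 1),
                "consensus": list(self.consensus),
                "fraction": self.fraction,
                "conserved80": self.conserved80,
                "conserved100": self.conserved100,
            }
        )


def column_conservation(a: MultipleAlignment) -> ColumnStats:
    """Column-wise consensus and conservation of a multiple alignment.

    The conservation fraction divides the modal non-gap residue count by the
    total number of taxa, so gapped taxa count against conservation; a column
    is flagged at >80% and at exactly 100%.
    """
    n = len(a.taxa)
    freqs = []
    consensus = []
    fraction = []
    c80 = []
    c100 = []
    for col in range(a.column_count):
        counter = Counter(row[col] for row in a.rows)
        freqs.append(dict(counter))
        nongap = {res: c for res, c in counter.items() if res != "-"}
        if nongap:
            top = max(nongap.items(), key=lambda kv: (kv[1], -ord(kv[0])))
            consensus.append(top[0])
            frac = top[1] / n
        else:
            consensus.append("-")
            frac = 0.0
        fraction.append(frac)
        c80.append(frac > 0.8)
        c100.append(frac == 1.0)
    return ColumnStats(
        tuple(freqs), "".join(consensus), tuple(fraction), tuple(c80), tuple(c100)
    )


def count_fully_conserved(a: MultipleAlignment) -> int:
    """Number of 100%-conserved columns (every taxon, same residue, no gap)."""
    return sum(column_conservation(a).conserved100)
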