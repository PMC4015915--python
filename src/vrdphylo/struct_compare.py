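"""Rigid-body comparison of polymerase Cα traces.

Implements the structural half of the pipeline: Kabsch least-squares
superposition, distance-based residue correspondence with sequence-order
(longest-increasing-subsequence) filtering, iterative refinement to a fixed
point, per-homomorph RMSD tables (the conservation comparison of the
helix-turn-helix thumb motif against the established palm motifs), a
Cα-geometry secondary-structure classifier, and detection of the cyclically
permuted (CAB) polymerase core found in birnaviral enzymes.

All coordinates are in Å.  Only proper rotations are ever returned:
reflections would invert molecular chirality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

try:  # biopython's 3-to-1 residue-name table
    from Bio.Data.PDBData import protein_letters_3to1_extended as _THREE_TO_ONE
except ImportError:  # pragma: no cover - older biopython layout
    from Bio.Data.SCOPData import protein_letters_3to1 as _THREE_TO_ONE

HOMOMORPH_IDS = ("hmG", "hmF", "hmA", "hmB", "hmC", "hmD", "hmE", "hmH")

#: default distance cutoff (Å) for residue correspondence
DEFAULT_CUTOFF = 4.0
#: iterative-refinement convergence tolerance (Å) and iteration cap
RMSD_TOL = 1e-3
MAX_ITER = 50


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentAnnotation:
    """A homomorph (conserved structural motif) as a residue-number range."""

    homomorph_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.homomorph_id not in HOMOMORPH_IDS:
            raise StructureError(f"unknown homomorph {self.homomorph_id!r}")
        if self.start_residue > self.end_residue:
            raise StructureError("segment start after end")


@dataclass(frozen=True)
class StructureModel:
    """An ordered Cα trace with residue identities.

    ``residue_numbers`` follow the source file (no renumbering) and must be
    non-decreasing; ``coords`` is an (n, 3) float array of Cα positions.
    """

    label: str
    residue_numbers: tuple[int, ...]
    sequence: str  # 1-letter codes, aligned with residue_numbers
    coords: np.ndarray
    segments: tuple[SegmentAnnotation, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.residue_numbers)
        if coords.shape != (n, 3) or len(self.sequence) != n:
            raise StructureError("residue numbers, sequence and coords disagree")
        if any(b < a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise StructureError("residue numbers must be non-decreasing")
        lo, hi = (min(self.residue_numbers), max(self.residue_numbers)) if n else (0, 0)
        for seg in self.segments:
            if seg.start_residue < lo or seg.end_residue > hi:
                raise StructureError(
                    f"segment {seg.homomorph_id} outside residue range of {self.label}"
                )

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def segment(self, homomorph_id: str) -> SegmentAnnotation | None:
        for seg in self.segments:
            if seg.homomorph_id == homomorph_id:
                return seg
        return None

    def segment_indices(self, seg: SegmentAnnotation) -> np.ndarray:
        nums = np.asarray(self.residue_numbers)
        return np.nonzero((nums >= seg.start_residue) & (nums <= seg.end_residue))[0]

    def with_segments(self, segments: Iterable[SegmentAnnotation]) -> "StructureModel":
        return StructureModel(
            self.label, self.residue_numbers, self.sequence, self.coords,
            tuple(segments),
        )


def parse_structure(pdb_text: str, chain: str, label: str | None = None) -> StructureModel:
    """Extract the Cα trace of one chain from legacy PDB text.

    Altloc conflicts are resolved by first occurrence; insertion-coded
    residues are kept in file order.
    """
    numbers: list[int] = []
    seq: list[str] = []
    coords: list[tuple[float, float, float]] = []
    seen: set[tuple[int, str]] = set()
    chain_found = False
    for line in pdb_text.splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            continue
        if line[21] != chain:
            continue
        chain_found = True
        if line[12:16].strip() != "CA" or line[76:78].strip() == "CA":
            continue  # want alpha carbons, not calcium
        resnum = int(line[22:26])
        icode = line[26]
        if (resnum, icode) in seen:
            continue  # first altloc occurrence wins
        seen.add((resnum, icode))
        numbers.append(resnum)
        seq.append(_THREE_TO_ONE.get(line[17:20].strip(), "X"))
        coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
    if not chain_found:
        raise StructureError(f"chain {chain!r} absent from file")
    if not coords:
        raise StructureError(f"no Cα atoms in chain {chain!r}")
    return StructureModel(
        label or f"chain_{chain}", tuple(numbers), "".join(seq), np.array(coords)
    )


def write_pdb(model: StructureModel, chain: str = "A") -> str:
    """Serialise a Cα trace as minimal legacy PDB text (ATOM records only)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if len(k) == 3}
    lines = []
    for i, (num, aa, xyz) in enumerate(
        zip(model.residue_numbers, model.sequence, model.coords), start=1
    ):
        res3 = one_to_three.get(aa, "GLY")
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:<3s} {chain}{num:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation/translation mapping set A onto set B."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "SuperpositionResult":
        rot = self.rotation.T
        return SuperpositionResult(rot, -rot @ self.translation, self.rmsd,
                                   self.n_matched)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of matched point sets (Kabsch/SVD).

    Minimises RMSD over proper rotations and translations mapping A onto B;
    a reflection is never returned.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise StructureError("matched (n, 3) point sets required")
    n = a.shape[0]
    if n < 3:
        raise StructureError("at least 3 matched points required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(np.vstack([a0, b0]), tol=1e-8) < 2:
        raise StructureError("points are collinear; rotation is not identifiable")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T)) or 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - rot @ ca
    diff = a @ rot.T + t - b
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rot, t, rmsd, n)


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Sequence-order-preserving residue pairing between two structures."""

    pairs: tuple[tuple[int, int], ...]  # 0-based positions in each residue list

    def __post_init__(self) -> None:
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if i2 <= i1 or j2 <= j1:
                raise StructureError("correspondence must increase in both sequences")

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, int), np.empty(0, int)
        arr = np.asarray(self.pairs, int)
        return arr[:, 0], arr[:, 1]


def _longest_increasing(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest subset strictly increasing in both coordinates (patience DP)."""
    pairs = sorted(pairs)
    best_len = [0] * len(pairs)
    prev = [-1] * len(pairs)
    for i, (ai, bi) in enumerate(pairs):
        best_len[i] = 1
        for j in range(i):
            aj, bj = pairs[j]
            if aj < ai and bj < bi and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not pairs:
        return []
    i = int(np.argmax(best_len))
    out = []
    while i >= 0:
        out.append(pairs[i])
        i = prev[i]
    return out[::-1]


def match_residues(
    a: StructureModel,
    b: StructureModel,
    sup: SuperpositionResult,
    cutoff: float = DEFAULT_CUTOFF,
) -> ResidueCorrespondence:
    """Mutually-nearest Cα pairs within ``cutoff`` after superposition,
    restricted to the longest subset increasing in both sequences."""
    if not cutoff > 0:
        raise StructureError("cutoff must be positive")
    moved = sup.apply(a.coords)
    tree_b = cKDTree(b.coords)
    tree_a = cKDTree(moved)
    d_ab, nn_ab = tree_b.query(moved, distance_upper_bound=cutoff)
    d_ba, nn_ba = tree_a.query(b.coords, distance_upper_bound=cutoff)
    candidates = [
        (i, int(j))
        for i, (d, j) in enumerate(zip(d_ab, nn_ab))
        if np.isfinite(d) and nn_ba[int(j)] == i
    ]
    return ResidueCorrespondence(tuple(_longest_increasing(candidates)))


def iterative_superpose(
    a: StructureModel,
    b: StructureModel,
    seed: ResidueCorrespondence,
    cutoff: float = DEFAULT_CUTOFF,
    tol: float = RMSD_TOL,
    max_iter: int = MAX_ITER,
    trace: list | None = None,
) -> tuple[SuperpositionResult, ResidueCorrespondence]:
    """Alternate superposition and re-matching until the RMSD stabilises.

    An iteration is accepted if it grows the correspondence or keeps its
    size while not increasing the RMSD; over accepted equal-size iterations
    the RMSD sequence is therefore non-increasing.  ``trace``, if supplied,
    collects (n_pairs, rmsd) for every accepted iteration.
    """
    if len(seed) < 3:
        raise StructureError("seed correspondence needs at least 3 pairs")
    corr = seed
    ia, ib = corr.indices()
    sup = kabsch_superpose(a.coords[ia], b.coords[ib])
    if trace is not None:
        trace.append((len(corr), sup.rmsd))
    for _ in range(max_iter):
        new_corr = match_residues(a, b, sup, cutoff)
        if len(new_corr) < 3:
            raise StructureError("correspondence collapsed below 3 pairs")
        ia, ib = new_corr.indices()
        new_sup = kabsch_superpose(a.coords[ia], b.coords[ib])
        if new_sup.rmsd > sup.rmsd + 1e-12 and len(new_corr) <= len(corr):
            break  # would degrade: keep the previous accepted state
        improved = abs(sup.rmsd - new_sup.rmsd) >= tol or len(new_corr) != len(corr)
        sup, corr = new_sup, new_corr
        if trace is not None:
            trace.append((len(corr), sup.rmsd))
        if not improved:
            break
    return sup, corr


# ---------------------------------------------------------------------------
# homomorph RMSD


def segment_rmsd(
    a: StructureModel,
    b: StructureModel,
    seg_a: SegmentAnnotation,
    seg_b: SegmentAnnotation,
    frame: str = "local",
    superposition: SuperpositionResult | None = None,
) -> float:
    """RMSD over one pair of equal-length homomorph segments.

    ``frame="local"`` superposes on the segment alone; ``frame="global"``
    applies a supplied whole-structure superposition without refitting.
    """
    ia = a.segment_indices(seg_a)
    ib = b.segment_indices(seg_b)
    if len(ia) != len(ib):
        raise StructureError(
            f"segment length mismatch: {len(ia)} vs {len(ib)} "
            f"({seg_a.homomorph_id})"
        )
    ca, cb = a.coords[ia], b.coords[ib]
    if frame == "local":
        return kabsch_superpose(ca, cb).rmsd
    if frame == "global":
        if superposition is None:
            raise StructureError("global frame requires a whole-structure superposition")
        diff = superposition.apply(ca) - cb
        return float(np.sqrt((diff ** 2).sum() / len(ia)))
    raise StructureError(f"unknown frame {frame!r}")


def homomorph_rmsd_table(
    structs: Sequence[StructureModel], hm: str, frame: str = "local"
) -> pd.DataFrame:
    """Pairwise segment RMSD matrix for one homomorph (NaN where undefined)."""
    labels = [s.label for s in structs]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    np.fill_diagonal(out.values, 0.0)
    for i, si in enumerate(structs):
        for j in range(i + 1, len(structs)):
            sj = structs[j]
            seg_i, seg_j = si.segment(hm), sj.segment(hm)
            if seg_i is None or seg_j is None:
                continue
            try:
                r = segment_rmsd(si, sj, seg_i, seg_j, frame=frame)
            except StructureError:
                continue  # unequal lengths: leave the pair missing
            out.iat[i, j] = out.iat[j, i] = r
    return out


# ---------------------------------------------------------------------------
# secondary structure (Cα-only geometric classifier)

# Distance windows (Å) on |Cα_i - Cα_{i+k}| for k = 2, 3, 4.  Helical traces
# sit near (5.4, 5.1, 6.2), extended strands near (6.7, 10, 13).
_HELIX_D2 = (4.9, 5.9)
_HELIX_D3 = (4.5, 5.7)
_HELIX_D4 = (5.3, 7.2)
_STRAND_D2 = 6.3
_STRAND_D3 = 8.5
_STRAND_D4 = 11.0


def assign_sse(s: StructureModel) -> str:
    """Per-residue secondary-structure string over {H, E, L}.

    A purely geometric Cα classifier (in the spirit of P-SEA): residue i is
    classified from the i..i+4 distance profile.  The two residues at each
    terminus default to loop.
    """
    n = len(s)
    if n < 5:
        raise StructureError("at least 5 residues required")
    x = s.coords
    cls = ["L"] * n
    d2 = np.linalg.norm(x[2:] - x[:-2], axis=1)
    d3 = np.linalg.norm(x[3:] - x[:-3], axis=1)
    d4 = np.linalg.norm(x[4:] - x[:-4], axis=1)
    for i in range(n - 4):
        if (
            _HELIX_D2[0] <= d2[i] <= _HELIX_D2[1]
            and _HELIX_D3[0] <= d3[i] <= _HELIX_D3[1]
            and _HELIX_D4[0] <= d4[i] <= _HELIX_D4[1]
        ):
            cls[i] = "H"
        elif d2[i] >= _STRAND_D2 and d3[i] >= _STRAND_D3 and d4[i] >= _STRAND_D4:
            cls[i] = "E"
    cls[:2] = ["L", "L"]
    cls[-2:] = ["L", "L"]
    return "".join(cls)


# ---------------------------------------------------------------------------
# motif order


def detect_permutation(segments: Sequence[SegmentAnnotation]) -> str:
    """Classify the polymerase core motif order from hmA/hmB/hmC positions.

    Returns "canonical_ABC", "permuted_CAB" (the birnaviral cyclic
    permutation), or "indeterminate".
    """
    starts: dict[str, int] = {}
    for seg in segments:
        if seg.homomorph_id in {"hmA", "hmB", "hmC"}:
            if seg.homomorph_id in starts:
                raise StructureError(f"duplicated motif {seg.homomorph_id}")
            starts[seg.homomorph_id] = seg.start_residue
    if set(starts) != {"hmA", "hmB", "hmC"}:
        return "indeterminate"
    order = [hm for hm, _ in sorted(starts.items(), key=lambda kv: kv[1])]
    if order == ["hmA", "hmB", "hmC"]:
        return "canonical_ABC"
    if order == ["hmC", "hmA", "hmB"]:
        return "permuted_CAB"
    return "indeterminate"
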