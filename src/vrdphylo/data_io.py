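"""Study-set tables, Z-score matrices, and standard character matrices.

This module handles the tabular inputs of the polymerase study: the curated
list of viral RNA-dependent polymerase (vRdP) structures, the pairwise
structural-similarity Z-score matrix produced by elastic structure
comparison, and the 21-feature discrete character matrix used as the
"morphological" partition of the combined Bayesian analysis.  It also applies
the representative-selection rules (at most two structures per genus,
preference for liganded, wild-type, high-resolution structures) and exports
MrBayes-compatible mixed NEXUS matrices.

European-style decimal commas, as used in the source tables, are accepted on
input everywhere; serialisation always uses decimal points.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

MISSING = None  # sentinel for a missing character state

_PDB_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

FEATURE_IDS = tuple("ABCDEFGHIJKLMNOPQRSTU")


class StudySetError(ValueError):
    """Raised for malformed or inconsistent study-set tables."""


def _parse_decimal(token: str, *, context: str = "") -> float:
    """Parse a number accepting both decimal comma and decimal point."""
    try:
        return float(token.strip().replace(",", "."))
    except ValueError:
        raise StudySetError(f"unparseable number {token!r} {context}".strip()) from None


@dataclass(frozen=True)
class PolymeraseRecord:
    """One study-set entry: a virus and the polymerase structure representing it."""

    virus_name: str
    abbreviation: str
    genus: str
    family: str
    baltimore_class: str  # one of {"III", "IV", "VI"}
    pdb_id: str
    chain: str
    resolution: float  # Angstrom
    cocrystallized: tuple[str, ...] = ()
    has_mutation: bool = False
    has_bound_template_or_substrate: bool = False

    def __post_init__(self) -> None:
        if not _PDB_RE.match(self.pdb_id):
            raise StudySetError(f"invalid PDB id {self.pdb_id!r}")
        if len(self.chain) != 1:
            raise StudySetError(f"chain must be a single character, got {self.chain!r}")
        if not self.resolution > 0:
            raise StudySetError(f"resolution must be positive, got {self.resolution}")
        if self.baltimore_class not in {"III", "IV", "VI"}:
            raise StudySetError(f"unknown Baltimore class {self.baltimore_class!r}")


@dataclass(frozen=True)
class StudySet:
    """An ordered collection of polymerase records with unique labels."""

    records: tuple[PolymeraseRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise StudySetError("empty study set")
        abbrs = [r.abbreviation for r in self.records]
        if len(set(abbrs)) != len(abbrs):
            dup = [a for a, n in Counter(abbrs).items() if n > 1]
            raise StudySetError(f"duplicate abbreviations: {dup}")
        keys = [(r.pdb_id, r.chain) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = [k for k, n in Counter(keys).items() if n > 1]
            raise StudySetError(f"duplicate (pdb_id, chain): {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.records)


@dataclass(frozen=True)
class SelectionRules:
    """Representative-selection policy applied per genus.

    At most ``max_per_genus`` structures (from distinct virus species) are
    retained per genus, with configured exceptions; candidates are ranked by
    bound substrate/template, absence of mutations, then resolution.
    """

    max_per_genus: int = 2
    genus_exceptions: Mapping[str, int] = field(
        default_factory=lambda: {"Enterovirus": 4}
    )
    prefer_liganded: bool = True
    prefer_high_resolution: bool = True
    prefer_wildtype: bool = True

    def __post_init__(self) -> None:
        if self.max_per_genus < 1 or any(v < 1 for v in self.genus_exceptions.values()):
            raise StudySetError("selection counts must be >= 1")

    def allowance(self, genus: str) -> int:
        return self.genus_exceptions.get(genus, self.max_per_genus)


def load_study_set(path: str | Path) -> StudySet:
    """Load a study-set table (TSV, header row mandatory).

    Resolutions may use decimal commas.  Duplicate (pdb_id, chain) pairs and
    unparseable numbers are hard errors naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise StudySetError("empty study set")
    records = []
    for idx, row in df.iterrows():
        ctx = f"(row {idx + 2} of {path})"
        cocry = tuple(x.strip() for x in row.get("cocrystallized", "").split(";") if x.strip())
        records.append(
            PolymeraseRecord(
                virus_name=row["virus"].strip(),
                abbreviation=row["abbreviation"].strip(),
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                baltimore_class=row["baltimore_class"].strip(),
                pdb_id=row["pdb_id"].strip(),
                chain=row["chain"].strip(),
                resolution=_parse_decimal(row["resolution"], context=ctx),
                cocrystallized=cocry,
                has_mutation=row.get("has_mutation", "0").strip() in {"1", "true", "True"},
                has_bound_template_or_substrate=row.get(
                    "has_bound_template_or_substrate", "0"
                ).strip()
                in {"1", "true", "True"},
            )
        )
    return StudySet(tuple(records))


def summarize_taxonomy(s: StudySet) -> dict[str, int]:
    """Count distinct species, genera, families and Baltimore classes."""
    return {
        "species": len({r.virus_name for r in s}),
        "genera": len({r.genus for r in s}),
        "families": len({r.family for r in s}),
        "baltimore_classes": len({r.baltimore_class for r in s}),
    }


def select_representatives(
    candidates: Sequence[PolymeraseRecord], rules: SelectionRules | None = None
) -> StudySet:
    """Apply the per-genus representative-selection rules.

    Within a genus, candidates are ranked by (bound template/substrate desc,
    mutation asc, resolution asc, pdb_id asc) and at most the allowed count is
    retained, never keeping two structures of the same virus species.  Output
    order is deterministic (family, genus, rank) and independent of the input
    ordering.
    """
    if not candidates:
        raise StudySetError("no candidates")
    rules = rules or SelectionRules()

    def rank_key(r: PolymeraseRecord):
        return (
            not r.has_bound_template_or_substrate if rules.prefer_liganded else False,
            r.has_mutation if rules.prefer_wildtype else False,
            r.resolution if rules.prefer_high_resolution else 0.0,
            r.pdb_id,
        )

    by_genus: dict[tuple[str, str], list[PolymeraseRecord]] = {}
    for r in candidates:
        by_genus.setdefault((r.family, r.genus), []).append(r)

    chosen: list[PolymeraseRecord] = []
    for (family, genus) in sorted(by_genus):
        allowed = rules.allowance(genus)
        seen_species: set[str] = set()
        for r in sorted(by_genus[(family, genus)], key=rank_key):
            if len(seen_species) >= allowed:
                break
            if r.virus_name in seen_species:
                continue
            seen_species.add(r.virus_name)
            chosen.append(r)
    return StudySet(tuple(chosen))


# ---------------------------------------------------------------------------
# Z-score matrix


@dataclass(frozen=True)
class ZScoreMatrix:
    """Symmetric pairwise structural-similarity Z-scores; diagonal undefined."""

    labels: tuple[str, ...]
    _z: Mapping[frozenset[str], float]

    def lookup(self, a: str, b: str) -> float:
        if a == b:
            raise KeyError("self-similarity is undefined")
        for lab in (a, b):
            if lab not in self.labels:
                raise KeyError(f"unknown label {lab!r}")
        return self._z[frozenset((a, b))]

    def pairs(self) -> list[tuple[tuple[str, str], float]]:
        """All defined unordered pairs (a, b) with a before b in label order."""
        order = {lab: i for i, lab in enumerate(self.labels)}
        out = []
        for key, z in self._z.items():
            a, b = sorted(key, key=order.__getitem__)
            out.append(((a, b), z))
        out.sort(key=lambda item: (order[item[0][0]], order[item[0][1]]))
        return out

    @property
    def max_z(self) -> float:
        return max(self._z.values())

    def to_frame(self) -> pd.DataFrame:
        """Full symmetric DataFrame (NaN diagonal), decimal points."""
        import numpy as np

        df = pd.DataFrame(np.nan, index=self.labels, columns=self.labels)
        for (a, b), z in self.pairs():
            df.loc[a, b] = z
            df.loc[b, a] = z
        return df


def load_zscore_matrix(path: str | Path) -> ZScoreMatrix:
    """Load a pairwise Z-score table (lower-triangular or full layout).

    Decimal commas and points are both accepted; "-" and empty cells mean
    undefined.  If both triangles are present they must agree; negative
    values are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    col_labels = [c.strip() for c in df.columns]
    row_labels = [str(r).strip() for r in df.index]
    labels = list(dict.fromkeys(col_labels + row_labels))
    z: dict[frozenset[str], float] = {}
    for r, row in zip(row_labels, df.itertuples(index=False)):
        for c, cell in zip(col_labels, row):
            tok = str(cell).strip()
            if tok in {"", "-", "nan"}:
                continue
            if r == c:
                continue  # diagonal is undefined
            val = _parse_decimal(tok, context=f"(cell {r}/{c})")
            if val < 0:
                raise StudySetError(f"negative Z-score at {r}/{c}: {val}")
            key = frozenset((r, c))
            if key in z and abs(z[key] - val) > 1e-9:
                raise StudySetError(
                    f"asymmetric entries for pair {r}/{c}: {z[key]} vs {val}"
                )
            z[key] = val
    return ZScoreMatrix(tuple(labels), z)


def write_zscore_matrix(m: ZScoreMatrix, path: str | Path) -> None:
    """Serialise as a full symmetric TSV with decimal points."""
    m.to_frame().to_csv(path, sep="\t", na_rep="-", float_format="%.1f")


def filter_pairs_by_zscore(
    m: ZScoreMatrix, threshold: float
) -> list[tuple[tuple[str, str], float]]:
    """All unordered pairs scoring strictly below ``threshold``, ascending.

    The study treats pairs with Z below 2 as incidental structural hits.
    """
    if not threshold > 0:
        if threshold == 0:
            return []
        raise ValueError("threshold must be positive")
    hits = [(pair, z) for pair, z in m.pairs() if z < threshold]
    hits.sort(key=lambda item: (item[1], item[0]))
    return hits


# ---------------------------------------------------------------------------
# Character matrix


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters matrix of unordered multistate (0-9) characters.

    ``states[i][j]`` is an int in 0..9 or :data:`MISSING`.  The study's
    packaged matrix has 21 characters (features A..U); the ordering mode is
    fixed to "unordered" (a state may change to any other in one step).
    """

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    states: tuple[tuple[int | None, ...], ...]
    ordering_mode: str = "unordered"

    def __post_init__(self) -> None:
        if self.ordering_mode != "unordered":
            raise StudySetError("only unordered characters are supported")
        if len(set(self.taxa)) != len(self.taxa):
            raise StudySetError("duplicate taxa in character matrix")
        for row in self.states:
            if len(row) != len(self.characters):
                raise StudySetError("ragged character matrix")
            for v in row:
                if v is not MISSING and not (0 <= v <= 9):
                    raise StudySetError(f"state {v} outside 0-9")
    def check_state_contiguity(self) -> None:
        """Warn for characters whose observed states are not 0..max."""
        for j, char in enumerate(self.characters):
            observed = {row[j] for row in self.states if row[j] is not MISSING}
            if observed and observed != set(range(max(observed) + 1)):
                warnings.warn(
                    f"character {char}: observed states {sorted(observed)} "
                    "are not contiguous from 0",
                    stacklevel=3,
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def state(self, taxon: str, character: str) -> int | None:
        return self.states[self.taxa.index(taxon)][self.characters.index(character)]

    def row(self, taxon: str) -> tuple[int | None, ...]:
        return self.states[self.taxa.index(taxon)]

    def state_counts(self) -> tuple[int, ...]:
        """Per-character number of states, ``max(observed) + 1`` (>= 2)."""
        counts = []
        for j in range(self.n_characters):
            observed = [row[j] for row in self.states if row[j] is not MISSING]
            counts.append(max(2, (max(observed) + 1) if observed else 2))
        return tuple(counts)


def load_character_matrix(path: str | Path) -> CharacterMatrix:
    """Load a character-state table; tokens "N" and "?" map to missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    taxa = tuple(str(t).strip() for t in df.index)
    characters = tuple(c.strip() for c in df.columns)
    states = []
    for taxon, row in zip(taxa, df.itertuples(index=False)):
        parsed: list[int | None] = []
        for char, cell in zip(characters, row):
            tok = str(cell).strip()
            if tok in {"N", "?"}:
                parsed.append(MISSING)
            elif len(tok) == 1 and tok.isdigit():
                parsed.append(int(tok))
            else:
                raise StudySetError(
                    f"invalid state token {tok!r} at taxon {taxon}, character {char}"
                )
        states.append(tuple(parsed))
    cm = CharacterMatrix(taxa, characters, tuple(states))
    cm.check_state_contiguity()
    return cm


def write_character_matrix(cm: CharacterMatrix, path: str | Path) -> None:
    rows = []
    for taxon, row in zip(cm.taxa, cm.states):
        rows.append([taxon] + ["?" if v is MISSING else str(v) for v in row])
    pd.DataFrame(rows, columns=["taxon", *cm.characters]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# NEXUS export / import (MrBayes-compatible mixed DATA block)


def write_nexus_mixed(
    aln=None,
    cm: CharacterMatrix | None = None,
    path: str | Path = "combined.nex",
) -> None:
    """Write a NEXUS DATA block with protein and/or standard partitions.

    ``aln`` is a :class:`vrdphylo.struct_align.MultipleAlignment` (or any
    object with ``taxa`` and ``rows``).  When both partitions are given the
    taxon sets must match and a mixed-datatype matrix is emitted.  Gaps are
    "-", missing states "?".
    """
    if aln is None and cm is None:
        raise StudySetError("at least one of alignment/character matrix required")
    if aln is not None and cm is not None:
        if set(aln.taxa) != set(cm.taxa):
            raise StudySetError("taxon sets of alignment and character matrix differ")

    taxa = list(aln.taxa) if aln is not None else list(cm.taxa)
    seq_part = {t: r for t, r in zip(aln.taxa, aln.rows)} if aln is not None else None
    char_part = (
        {
            t: "".join("?" if v is MISSING else str(v) for v in row)
            for t, row in zip(cm.taxa, cm.states)
        }
        if cm is not None
        else None
    )
    n_seq = len(next(iter(seq_part.values()))) if seq_part else 0
    n_chr = len(next(iter(char_part.values()))) if char_part else 0
    nchar = n_seq + n_chr
    if seq_part and char_part:
        datatype = f"mixed(protein:1-{n_seq},standard:{n_seq + 1}-{nchar})"
    elif seq_part:
        datatype = "protein"
    else:
        datatype = "standard"

    pad = max(len(t) for t in taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(taxa)} NCHAR={nchar};",
        f"    FORMAT DATATYPE={datatype} GAP=- MISSING=?;",
        "    MATRIX",
    ]
    for t in taxa:
        row = (seq_part[t] if seq_part else "") + (char_part[t] if char_part else "")
        lines.append(f"        {t:<{pad}}{row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_mixed(path: str | Path):
    """Read back a NEXUS file written by :func:`write_nexus_mixed`.

    Returns ``(sequences, character_matrix)``; either element may be None.
    ``sequences`` is a dict label -> gapped string.
    """
    text = Path(path).read_text()
    fmt = re.search(r"DATATYPE\s*=\s*(\S+)", text, re.IGNORECASE)
    if not fmt:
        raise StudySetError("no DATATYPE in NEXUS file")
    datatype = fmt.group(1).rstrip(";")
    matrix = re.search(r"MATRIX(.*?);", text, re.DOTALL | re.IGNORECASE)
    if not matrix:
        raise StudySetError("no MATRIX block")
    rows: dict[str, str] = {}
    for line in matrix.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        label, seq = line.split(None, 1)
        rows[label] = rows.get(label, "") + seq.replace(" ", "")

    mixed = re.match(r"mixed\(protein:1-(\d+),standard:(\d+)-(\d+)\)", datatype, re.I)
    seqs: dict[str, str] | None = None
    cm: CharacterMatrix | None = None

    def parse_standard(block: dict[str, str]) -> CharacterMatrix:
        taxa = tuple(block)
        chars = tuple(str(i + 1) for i in range(len(next(iter(block.values())))))
        states = tuple(
            tuple(MISSING if ch in "?-" else int(ch) for ch in row)
            for row in block.values()
        )
        return CharacterMatrix(taxa, chars, states)

    if mixed:
        n_seq = int(mixed.group(1))
        seqs = {t: r[:n_seq] for t, r in rows.items()}
        cm = parse_standard({t: r[n_seq:] for t, r in rows.items()})
    elif datatype.lower() == "protein":
        seqs = rows
    elif datatype.lower() == "standard":
        cm = parse_standard(rows)
    else:
        raise StudySetError(f"unsupported DATATYPE {datatype!r}")
    return seqs, cm
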