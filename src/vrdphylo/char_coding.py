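"""Deterministic encoding of the 21 structural/biochemical polymerase features.

Each viral polymerase is described by a set of raw measurements (biochemical
facts such as product type and initiation mode, plus structural observations
such as motif secondary-structure composition and inter-motif connection
lengths).  The features, labelled A..U, are encoded to unordered multistate
characters (0-9) for the standard-data partition of the Bayesian analysis.

Secondary-structure token strings use one character per element:
``a`` = alpha helix, ``b`` = beta strand, ``g`` = 3_10 helix, ``l`` = loop.
Unicode forms ("α", "β", "3_10", "310") are normalised on input.

Threshold conventions where the published feature descriptions leave a gap:

* feature K (motif B helix length): "long" starts at 22 residues;
* feature N (motif C length): "short" means <= 10 residues;
* feature R (D-E connection): "long structured" means >= 20 residues;
* feature T (thumb size): "small" means <= 180 residues (strict ">180" for
  large);
* feature M: a B-C connection of >= 15 residues counts as "long helical"
  only when it contains a helix of >= 8 residues, otherwise it is coded as a
  loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .data_io import MISSING, FEATURE_IDS, CharacterMatrix

logger = logging.getLogger(__name__)

#: legal state range (inclusive upper bound) per feature
STATE_RANGES: dict[str, int] = {
    "A": 1, "B": 1, "C": 2, "D": 1, "E": 1, "F": 2, "G": 2, "H": 1, "I": 2,
    "J": 2, "K": 1, "L": 1, "M": 2, "N": 1, "O": 1, "P": 2, "Q": 1, "R": 1,
    "S": 1, "T": 1, "U": 3,
}


def normalize_sse(tokens: str | Iterable[str] | None) -> str | None:
    """Normalise a secondary-structure token string to the a/b/g/l alphabet."""
    if tokens is None:
        return None
    if not isinstance(tokens, str):
        tokens = " ".join(tokens)
    s = tokens.replace("α", "a").replace("β", "b").replace("₁₀", "_10")
    s = s.replace("3_10", "g").replace("310", "g").replace("3-10", "g")
    s = s.replace(" ", "").replace("(", "").replace(")", "").replace("-", "")
    s = s.lower()
    if not set(s) <= set("abgl"):
        raise ValueError(f"unrecognised secondary-structure tokens in {tokens!r}")
    return s


@dataclass(frozen=True)
class FeatureMeasurement:
    """Raw measurements for one polymerase; unknown fields stay None."""

    product_type: str | None = None          # "RNA" | "DNA"
    template_type: str | None = None         # "RNA" | "DNA_and_RNA"
    initiation: str | None = None            # "de_novo" | "protein_primer" | "RNA_primer"
    architecture: str | None = None          # "encircled" | "open"
    core_order: str | None = None            # "ABC" | "CAB"
    f2_present: bool | None = None
    insertion_present: bool | None = None
    motifF_structure: str | None = None      # SSE token string
    fa_connection_length: int | None = None  # residues
    motifA_structure: str | None = None
    ab_connection_structure: str | None = None
    motifB_helix_length: int | None = None
    motifB_kink: bool | None = None
    bc_connection_length: int | None = None
    bc_helix_length: int | None = None       # longest helix inside the B-C connection
    motifC_length: int | None = None
    cd_connection_length: int | None = None
    motifD_structure: str | None = None
    motifD_helix_shifted: bool | None = None
    de_connection_length: int | None = None
    motifE_width: str | None = None          # "wide" | "narrow"
    thumb_size: int | None = None            # residues
    priming_motif: str | None = None         # "none" | "loop_in_thumb" | "loop_in_palm" | "C_terminal"

    def merged(self, other: "FeatureMeasurement") -> "FeatureMeasurement":
        """Overlay non-None fields of ``other`` onto this measurement."""
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for f in fields(other):
            v = getattr(other, f.name)
            if v is not None:
                data[f.name] = v
        return FeatureMeasurement(**data)


def _missing(feature: str, field_name: str):
    warnings.warn(
        f"feature {feature}: required measurement {field_name!r} absent; "
        "coding as missing",
        stacklevel=3,
    )
    return MISSING


def _match_sse(feature: str, observed: str | None, patterns: dict[int, tuple[str, ...]],
               field_name: str):
    if observed is None:
        return _missing(feature, field_name)
    norm = normalize_sse(observed)
    for state, pats in patterns.items():
        if norm in pats:
            return state
    warnings.warn(
        f"feature {feature}: structure {observed!r} matches no defined state; "
        "coding as missing",
        stacklevel=3,
    )
    return MISSING


_ENUMS = {
    "A": ("product_type", {"RNA": 0, "DNA": 1}),
    "B": ("template_type", {"RNA": 0, "DNA_and_RNA": 1}),
    "C": ("initiation", {"de_novo": 0, "protein_primer": 1, "RNA_primer": 2}),
    "D": ("architecture", {"encircled": 0, "open": 1}),
    "E": ("core_order", {"ABC": 0, "CAB": 1}),
    "S": ("motifE_width", {"wide": 0, "narrow": 1}),
    "U": ("priming_motif", {"none": 0, "loop_in_thumb": 1, "loop_in_palm": 2,
                            "C_terminal": 3}),
}

_SSE_PATTERNS = {
    "G": ("motifF_structure", {0: ("bbab", "bbgb"), 1: ("bbb",), 2: ("bb",)}),
    "I": ("motifA_structure", {0: ("g",), 1: ("ba",), 2: ("bg",)}),
    "J": ("ab_connection_structure", {0: ("aabb",), 1: ("abbabb",), 2: ("bb",)}),
    "P": ("motifD_structure", {0: ("ga",), 1: ("a",), 2: ("ab",)}),
}


def encode_character(feature: str, m: FeatureMeasurement):
    """Encode one feature from a measurement; returns a state or MISSING."""
    if feature not in STATE_RANGES:
        raise KeyError(f"unknown feature {feature!r}")

    if feature in _ENUMS:
        field_name, table = _ENUMS[feature]
        value = getattr(m, field_name)
        if value is None:
            return _missing(feature, field_name)
        if value not in table:
            raise ValueError(f"feature {feature}: illegal value {value!r}")
        return table[value]

    if feature in _SSE_PATTERNS:
        field_name, patterns = _SSE_PATTERNS[feature]
        return _match_sse(feature, getattr(m, field_name), patterns, field_name)

    if feature == "F":
        if m.insertion_present is None or m.f2_present is None:
            return _missing(feature, "f2_present/insertion_present")
        if m.insertion_present:
            return 2
        return 0 if m.f2_present else 1
    if feature == "H":
        if m.fa_connection_length is None:
            return _missing(feature, "fa_connection_length")
        return 0 if m.fa_connection_length <= 35 else 1
    if feature == "K":
        if m.motifB_helix_length is None:
            return _missing(feature, "motifB_helix_length")
        return 0 if m.motifB_helix_length <= 21 else 1
    if feature == "L":
        if m.motifB_kink is None:
            return _missing(feature, "motifB_kink")
        return int(bool(m.motifB_kink))
    if feature == "M":
        if m.bc_connection_length is None:
            return _missing(feature, "bc_connection_length")
        if m.bc_connection_length <= 5:
            return 0
        helix = m.bc_helix_length or 0
        if m.bc_connection_length >= 15 and helix >= 8:
            return 2
        return 1
    if feature == "N":
        if m.motifC_length is None:
            return _missing(feature, "motifC_length")
        return 0 if m.motifC_length <= 10 else 1
    if feature == "O":
        if m.cd_connection_length is None:
            return _missing(feature, "cd_connection_length")
        return 0 if m.cd_connection_length <= 5 else 1
    if feature == "Q":
        if m.motifD_helix_shifted is None:
            return _missing(feature, "motifD_helix_shifted")
        return int(bool(m.motifD_helix_shifted))
    if feature == "R":
        if m.de_connection_length is None:
            return _missing(feature, "de_connection_length")
        return 0 if m.de_connection_length < 20 else 1
    if feature == "T":
        if m.thumb_size is None:
            return _missing(feature, "thumb_size")
        return 0 if m.thumb_size > 180 else 1
    raise AssertionError(f"unhandled feature {feature}")  # pragma: no cover


@dataclass(frozen=True)
class CharacterVector:
    """The encoded 21-state row for one polymerase."""

    taxon: str
    states: Mapping[str, int | None]

    def __post_init__(self) -> None:
        for f, s in self.states.items():
            if s is not MISSING and not (0 <= s <= STATE_RANGES[f]):
                raise ValueError(f"state {s} illegal for feature {f}")

    def as_tuple(self) -> tuple[int | None, ...]:
        return tuple(self.states[f] for f in FEATURE_IDS)


def encode_polymerase(m: FeatureMeasurement, taxon: str = "") -> CharacterVector:
    """Encode all 21 features A..U for one measurement set."""
    return CharacterVector(taxon, {f: encode_character(f, m) for f in FEATURE_IDS})


# representative values per (feature, state); all round-trip through
# encode_character by construction
_REPRESENTATIVE: dict[str, dict[int, dict]] = {
    "A": {0: {"product_type": "RNA"}, 1: {"product_type": "DNA"}},
    "B": {0: {"template_type": "RNA"}, 1: {"template_type": "DNA_and_RNA"}},
    "C": {0: {"initiation": "de_novo"}, 1: {"initiation": "protein_primer"},
          2: {"initiation": "RNA_primer"}},
    "D": {0: {"architecture": "encircled"}, 1: {"architecture": "open"}},
    "E": {0: {"core_order": "ABC"}, 1: {"core_order": "CAB"}},
    "F": {0: {"f2_present": True, "insertion_present": False},
          1: {"f2_present": False, "insertion_present": False},
          2: {"f2_present": True, "insertion_present": True}},
    "G": {0: {"motifF_structure": "bbab"}, 1: {"motifF_structure": "bbb"},
          2: {"motifF_structure": "bb"}},
    "H": {0: {"fa_connection_length": 30}, 1: {"fa_connection_length": 50}},
    "I": {0: {"motifA_structure": "g"}, 1: {"motifA_structure": "ba"},
          2: {"motifA_structure": "bg"}},
    "J": {0: {"ab_connection_structure": "aabb"},
          1: {"ab_connection_structure": "abbabb"},
          2: {"ab_connection_structure": "bb"}},
    "K": {0: {"motifB_helix_length": 20}, 1: {"motifB_helix_length": 25}},
    "L": {0: {"motifB_kink": False}, 1: {"motifB_kink": True}},
    "M": {0: {"bc_connection_length": 4},
          1: {"bc_connection_length": 10},
          2: {"bc_connection_length": 18, "bc_helix_length": 9}},
    "N": {0: {"motifC_length": 10}, 1: {"motifC_length": 14}},
    "O": {0: {"cd_connection_length": 4}, 1: {"cd_connection_length": 8}},
    "P": {0: {"motifD_structure": "ga"}, 1: {"motifD_structure": "a"},
          2: {"motifD_structure": "ab"}},
    "Q": {0: {"motifD_helix_shifted": False}, 1: {"motifD_helix_shifted": True}},
    "R": {0: {"de_connection_length": 15}, 1: {"de_connection_length": 25}},
    "S": {0: {"motifE_width": "wide"}, 1: {"motifE_width": "narrow"}},
    "T": {0: {"thumb_size": 210}, 1: {"thumb_size": 160}},
    "U": {0: {"priming_motif": "none"}, 1: {"priming_motif": "loop_in_thumb"},
          2: {"priming_motif": "loop_in_palm"}, 3: {"priming_motif": "C_terminal"}},
}


def legal_states(feature: str) -> tuple[int, ...]:
    return tuple(range(STATE_RANGES[feature] + 1))


def representative_measurement(feature: str, state: int) -> FeatureMeasurement:
    """A measurement fragment guaranteed to encode back to ``state``."""
    if feature not in _REPRESENTATIVE:
        raise KeyError(f"unknown feature {feature!r}")
    if state not in _REPRESENTATIVE[feature]:
        raise ValueError(f"state {state} illegal for feature {feature}")
    return FeatureMeasurement(**_REPRESENTATIVE[feature][state])


# ---------------------------------------------------------------------------
# measurement fixtures


def load_measurements(path: str | Path) -> dict[str, FeatureMeasurement]:
    """Load per-taxon measurements from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    valid = {f.name for f in fields(FeatureMeasurement)}
    out = {}
    for taxon, entries in raw.items():
        unknown = set(entries) - valid
        if unknown:
            raise ValueError(f"{taxon}: unknown measurement fields {sorted(unknown)}")
        out[taxon] = FeatureMeasurement(**entries)
    return out


def encode_measurements(
    measurements: Mapping[str, FeatureMeasurement]
) -> CharacterMatrix:
    """Encode a full study set of measurements to a character matrix."""
    taxa = tuple(measurements)
    states = tuple(
        encode_polymerase(m, taxon=t).as_tuple() for t, m in measurements.items()
    )
    return CharacterMatrix(taxa, FEATURE_IDS, states)
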