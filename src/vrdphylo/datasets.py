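"""Accessors for the packaged machine-readable replicas of the study tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import data_io


def _data_path(name: str) -> Path:
    return Path(resources.files("vrdphylo") / "data" / name)


def study_set_path() -> Path:
    """TSV replica of the curated 22-structure polymerase list."""
    return _data_path("table1_polymerases.tsv")


def zscore_path() -> Path:
    """TSV replica of the pairwise structural Z-score matrix (comma decimals)."""
    return _data_path("table2_zscores.tsv")


def character_matrix_path() -> Path:
    """TSV replica of the 22 x 21 structural/biochemical character matrix."""
    return _data_path("table3_characters.tsv")


def measurements_path() -> Path:
    """Synthetic per-taxon feature measurements (see file header)."""
    return _data_path("feature_measurements_synthetic.yaml")


def load_study_set() -> data_io.StudySet:
    return data_io.load_study_set(study_set_path())


def load_zscores() -> data_io.ZScoreMatrix:
    return data_io.load_zscore_matrix(zscore_path())


def load_characters() -> data_io.CharacterMatrix:
    return data_io.load_character_matrix(character_matrix_path())
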