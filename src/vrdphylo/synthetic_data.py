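"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for random bifurcating trees (Yule process), residue alignments
evolved under a reversible model with gamma/invariant rate variation,
unordered multistate characters evolved under the symmetric Mk process, and
toy Cα traces with designed secondary structure and known rigid-body
perturbations.  Every generator is a pure function of its inputs and seed;
a single study seed fans out to per-component substreams so adding one
simulator never perturbs another's output.

The default character-state profile (13 binary, 7 ternary, 1 quaternary
characters) mirrors the observed state counts of the packaged 21-character
polymerase matrix.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass
from typing import Sequence

import numpy as np

import dendropy
from dendropy.simulate import treesim

from .data_io import CharacterMatrix
from .phylo_engine.substitution import RateHeterogeneity, SubstitutionModel
from .phylo_engine.tree import Tree
from .struct_compare import StructureModel

#: state-count profile of the packaged character matrix
TABLE_PROFILE: tuple[int, ...] = (2,) * 13 + (3,) * 7 + (4,)


def substream(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component random substream of a study seed."""
    key = int.from_bytes(component.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Everything needed to score a recovery experiment without re-simulation."""

    tree: Tree | None = None
    model: SubstitutionModel | None = None
    heterogeneity: RateHeterogeneity | None = None
    site_rates: np.ndarray | None = None
    invariant_flags: np.ndarray | None = None
    root_states: np.ndarray | None = None
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, scale: float = 1.0
) -> Tree:
    """Unrooted binary tree from a Yule (pure-birth) process.

    Branch lengths are Yule waiting times multiplied by ``scale``, giving
    expected substitutions per site.  The process is run to the n-th birth
    and then extended by one further exponential waiting time, so terminal
    branches are strictly positive and the expected total (unrooted) tree
    length is ``scale * (n_taxa - 1) / birth_rate``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    stream = substream(seed, "tree")
    rng = _pyrandom.Random(int(stream.integers(2**31)))
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    dt = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=ns,
        rng=rng,
    )
    extra = stream.exponential(1.0 / (n_taxa * birth_rate))
    for leaf in dt.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for edge in dt.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Tree.from_dendropy(dt, taxa=sorted(taxa))


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    tree: Tree,
    model: SubstitutionModel,
    heterogeneity: RateHeterogeneity | None,
    length: int,
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """Evolve an alignment along the tree; returns rows and ground truth.

    Root states are drawn from the stationary frequencies; each site gets a
    rate category (or the invariant class) and states evolve by the model's
    transition probabilities down every branch.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if model.alphabet is None:
        raise ValueError("model needs an alphabet")
    rng = substream(seed, "sequences")
    n = model.n_states
    pi = model.stationary_frequencies
    if heterogeneity is None:
        site_rates = np.ones(length)
        invariant = np.zeros(length, dtype=bool)
    else:
        rates, _ = heterogeneity.mixture_rates()
        invariant = rng.random(length) < heterogeneity.p_invariant
        cats = rng.integers(heterogeneity.n_categories, size=length)
        site_rates = np.where(invariant, 0.0, rates[cats])
    states = {tree.root: rng.choice(n, size=length, p=pi)}
    root_states = states[tree.root].copy()
    for v in tree.postorder()[::-1]:
        v = int(v)
        if v == tree.root:
            continue
        parent_states = states[int(tree.parent[v])]
        child = parent_states.copy()
        variable = site_rates > 0
        if variable.any():
            eff = np.unique(site_rates[variable] * tree.blen[v])
            for e in eff:
                sel = variable & np.isclose(site_rates * tree.blen[v], e)
                p = model.transition_matrices(np.asarray(e))
                cum = np.cumsum(p[parent_states[sel]], axis=1)
                u = rng.random(sel.sum())
                child[sel] = (u[:, None] < cum).argmax(axis=1)
        states[v] = child
    alphabet = model.alphabet
    rows = {
        tree.taxa[i]: "".join(alphabet[s] for s in states[i])
        for i in range(tree.n_leaves)
    }
    truth = GroundTruth(tree=tree, model=model, heterogeneity=heterogeneity,
                        site_rates=site_rates, invariant_flags=invariant,
                        root_states=root_states, seed=seed)
    return rows, truth


# ---------------------------------------------------------------------------
# standard characters


def simulate_characters(
    tree: Tree,
    state_counts: Sequence[int] = TABLE_PROFILE,
    seed: int = 0,
    reject_constant: bool = False,
    max_tries: int = 1000,
) -> tuple[CharacterMatrix, GroundTruth]:
    """Evolve unordered multistate characters under the symmetric Mk model.

    With ``reject_constant`` each character is redrawn until variable among
    the leaves (fixtures for variable-coding analyses).
    """
    if any(k < 2 for k in state_counts):
        raise ValueError("state counts must be >= 2")
    rng = substream(seed, "characters")
    n_leaves = tree.n_leaves
    post = tree.postorder()

    def draw(k: int) -> np.ndarray:
        states = np.empty(tree.n_nodes, dtype=np.int64)
        states[tree.root] = rng.integers(k)
        for v in post[::-1]:
            v = int(v)
            if v == tree.root:
                continue
            p = states[int(tree.parent[v])]
            t = tree.blen[v]
            e = np.exp(-k * t / (k - 1))
            p_same = 1.0 / k + (k - 1.0) / k * e
            if rng.random() < p_same:
                states[v] = p
            else:
                others = [s for s in range(k) if s != p]
                states[v] = others[int(rng.integers(k - 1))]
        return states[:n_leaves]

    columns = []
    for k in state_counts:
        for _ in range(max_tries):
            col = draw(int(k))
            if not reject_constant or len(set(col.tolist())) > 1:
                break
        else:
            raise RuntimeError("could not draw a variable character")
        columns.append(col)
    chars = tuple(f"c{j + 1}" for j in range(len(state_counts)))
    states = tuple(
        tuple(int(columns[j][i]) for j in range(len(state_counts)))
        for i in range(n_leaves)
    )
    cm = CharacterMatrix(tree.taxa, chars, states)
    return cm, GroundTruth(tree=tree, seed=seed)


# ---------------------------------------------------------------------------
# structures

_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_CA_STEP = 3.8
_HELIX_RADIUS = float(np.sqrt(_CA_STEP**2 - _HELIX_RISE**2)
                      / (2 * np.sin(_HELIX_TWIST / 2)))


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        _HELIX_RADIUS * np.cos(i * _HELIX_TWIST),
        _HELIX_RADIUS * np.sin(i * _HELIX_TWIST),
        _HELIX_RISE * i,
    ])


def _strand_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    dy = 0.5
    dx = float(np.sqrt(_CA_STEP**2 - (2 * dy) ** 2))
    return np.column_stack([dx * i, dy * (-1.0) ** i, np.zeros(n)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_structure(design: str, seed: int = 0) -> StructureModel:
    """Idealised Cα trace following a secondary-structure design string.

    ``design`` is a string over H (helix: 1.5 Å rise, 100° twist),
    E (near-straight strand) and L (self-avoiding random walk); segments
    are chained with a consistent 3.8 Å Cα-Cα step.
    """
    if len(design) < 5:
        raise ValueError("design must have at least 5 residues")
    if set(design) - set("HEL"):
        raise ValueError(f"unknown class tokens in {design!r}")
    rng = substream(seed, "structure")
    coords: list[np.ndarray] = []
    i = 0
    while i < len(design):
        j = i
        while j < len(design) and design[j] == design[i]:
            j += 1
        seg_len = j - i
        cls = design[i]
        if cls == "H":
            seg = _helix_coords(seg_len)
        elif cls == "E":
            seg = _strand_coords(seg_len)
        else:
            seg = np.zeros((seg_len, 3))
            pos = np.zeros(3)
            prev_dir = None
            for t in range(1, seg_len):
                for _ in range(100):
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    if prev_dir is None or np.dot(d, prev_dir) > -0.3:
                        break
                pos = pos + _CA_STEP * d
                seg[t] = pos
                prev_dir = d
        # orient the segment randomly and chain it to the previous one
        rot = _random_rotation(rng)
        seg = seg @ rot.T
        if coords:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            offset = coords[-1] + _CA_STEP * d - seg[0]
            seg = seg + offset
        coords.extend(seg)
        i = j
    arr = np.asarray(coords)
    seq = "".join("A" if c == "H" else ("V" if c == "E" else "G")
                  for c in design)
    return StructureModel(
        f"synthetic_{seed}", tuple(range(1, len(design) + 1)), seq, arr
    )


def perturb_structure(
    s: StructureModel,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """Apply a rigid transform then isotropic Gaussian coordinate noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = substream(seed, "perturb")
    if rotation is None:
        rotation = _random_rotation(substream(seed, "perturb-rot"))
    rotation = np.asarray(rotation, dtype=float)
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthonormal")
    if translation is None:
        translation = np.zeros(3)
    translation = np.asarray(translation, dtype=float)
    coords = s.coords @ rotation.T + translation
    if noise_sigma > 0:
        coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)
    out = StructureModel(f"{s.label}_perturbed", s.residue_numbers, s.sequence,
                         coords, s.segments)
    truth = GroundTruth(rotation=rotation, translation=translation, seed=seed)
    return out, truth
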