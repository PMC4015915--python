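"""Phylogenetic likelihoods by pruning (post-order dynamic programming).

Two routes share the tree machinery:

* a general dense route for any reversible n-state model with discrete-gamma
  plus invariant-sites rate mixing (used for the protein partition), and
* a fast closed-form route for symmetric k-state (Mk) characters, where the
  transition probability needs no matrix exponential:
  ``P(same) = 1/k + (k-1)/k * exp(-k t / (k-1))``.

Standard characters are by default conditioned on being variable (the Mkv
correction): each character's likelihood is divided by the probability of a
variable pattern, ``1 - sum over constant patterns``, which for the
symmetric model is ``1 - k * L(constant)``.

Gaps, "?" and other ambiguity codes contribute a flat partial likelihood
over all states.  No numerical rescaling is applied during pruning; with
double precision this is safe for the tree sizes this package targets
(hundreds of taxa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ..data_io import MISSING, CharacterMatrix
from .substitution import RateHeterogeneity, SubstitutionModel
from .tree import Tree

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# generic reversible-model route


def _compress_columns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts; columns shape (L, S)."""
    patterns, counts = np.unique(columns, axis=1, return_counts=True)
    return patterns, counts


def tip_partials(
    taxa: Sequence[str],
    data: Mapping[str, str],
    alphabet: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Compressed tip partial likelihoods.

    Returns ``(partials, counts)`` with partials of shape
    (n_taxa, n_states, n_patterns).  Characters outside the alphabet
    (gaps, ?, X, ...) are fully ambiguous.
    """
    lookup = {ch: i for i, ch in enumerate(alphabet)}
    n = len(alphabet)
    lengths = {len(data[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    cols = np.array(
        [[lookup.get(ch, -1) for ch in data[t]] for t in taxa], dtype=np.int64
    )
    patterns, counts = _compress_columns(cols)
    n_pat = patterns.shape[1]
    partials = np.zeros((len(taxa), n, n_pat))
    for i in range(len(taxa)):
        obs = patterns[i]
        ambiguous = obs < 0
        partials[i, :, ambiguous] = 1.0
        ok = ~ambiguous
        partials[i, obs[ok], np.nonzero(ok)[0]] = 1.0
    return partials, counts


def _prune_generic(
    tree: Tree,
    partials: np.ndarray,  # (L, n, P)
    model: SubstitutionModel,
    rates: np.ndarray,
) -> np.ndarray:
    """Per-category per-pattern likelihoods at the root; shape (C, P)."""
    n_cat = len(rates)
    n = model.n_states
    n_pat = partials.shape[2]
    eff = np.multiply.outer(tree.blen, rates)  # (nodes, C)
    pmats = model.transition_matrices(eff)  # (nodes, C, n, n)
    post = tree.postorder()
    buf = np.empty((tree.n_nodes, n_cat, n, n_pat))
    buf[: tree.n_leaves] = partials[:, None, :, :]
    for v in post:
        v = int(v)
        if tree.is_leaf(v):
            continue
        children = tree.children[v]
        acc = np.matmul(pmats[children[0]], buf[children[0]])
        for c in children[1:]:
            acc *= np.matmul(pmats[c], buf[c])
        buf[v] = acc
    pi = model.stationary_frequencies
    return np.einsum("i,cip->cp", pi, buf[tree.root])


def tree_log_likelihood(
    tree: Tree,
    data: Mapping[str, str],
    model: SubstitutionModel,
    heterogeneity: RateHeterogeneity | None = None,
) -> float:
    """Log likelihood of aligned columns on an unrooted tree.

    Mixes discrete-gamma categories and the invariant-sites class; an
    impossible configuration (e.g. all sites invariant but a variable
    column observed) yields ``-inf`` rather than an exception.
    """
    if model.alphabet is None:
        raise ValueError("model needs an alphabet to map sequence data")
    missing = set(data) - set(tree.taxa)
    if missing:
        raise ValueError(f"data taxa not in tree: {sorted(missing)}")
    partials, counts = tip_partials(tree.taxa, data, model.alphabet)
    if heterogeneity is None:
        rates = np.ones(1)
        weights = np.ones(1)
        p_inv = 0.0
    else:
        rates, weights = heterogeneity.mixture_rates()
        p_inv = heterogeneity.p_invariant
    cat_liks = _prune_generic(tree, partials, model, rates)  # (C, P)
    site = weights @ cat_liks
    if p_inv > 0:
        pi = model.stationary_frequencies
        inv = pi @ np.prod(partials, axis=0)  # (P,)
        site = site + p_inv * inv
    with np.errstate(divide="ignore"):
        logs = np.log(site)
    return float(np.dot(counts, logs))


# ---------------------------------------------------------------------------
# symmetric Mk route for standard characters


@dataclass(frozen=True)
class MkSettings:
    """Options for the standard-character partition."""

    variable_coding: bool = True  # Mkv: condition on characters being variable


_PAD = 10  # partials padded to the maximal standard-state count


@dataclass(frozen=True)
class CharacterData:
    """Preprocessed standard characters ready for repeated pruning."""

    taxa: tuple[str, ...]
    n_sites: int  # real characters (augmented constant sites excluded)
    k: np.ndarray  # per-site state count, augmented sites included
    tip: np.ndarray  # (L, PAD, S) tip partials
    mask: np.ndarray  # (PAD, S) valid-state indicator
    kfac: np.ndarray  # k/(k-1) per site
    inv_k: np.ndarray  # 1/k per site
    const_site_of_k: Mapping[int, int]  # k -> augmented all-zero site index
    variable_coding: bool

    @classmethod
    def from_matrix(
        cls,
        cm: CharacterMatrix,
        settings: MkSettings | None = None,
        state_counts: Sequence[int] | None = None,
    ) -> "CharacterData":
        settings = settings or MkSettings()
        ks = list(state_counts) if state_counts is not None else list(cm.state_counts())
        if len(ks) != cm.n_characters:
            raise ValueError("one state count per character required")
        if any(k < 2 for k in ks):
            raise ValueError("state counts must be >= 2")
        if settings.variable_coding:
            for j in range(cm.n_characters):
                observed = {row[j] for row in cm.states if row[j] is not MISSING}
                if len(observed) < 2:
                    raise ValueError(
                        f"character {cm.characters[j]} is constant: zero "
                        "probability under variable coding"
                    )
        n_real = cm.n_characters
        const_of_k: dict[int, int] = {}
        aug_ks: list[int] = []
        if settings.variable_coding:
            for k in sorted(set(ks)):
                const_of_k[k] = n_real + len(aug_ks)
                aug_ks.append(k)
        all_ks = np.array(ks + aug_ks, dtype=np.int64)
        s_tot = len(all_ks)
        n_taxa = cm.n_taxa
        tip = np.zeros((n_taxa, _PAD, s_tot))
        mask = np.zeros((_PAD, s_tot))
        for s in range(s_tot):
            mask[: all_ks[s], s] = 1.0
        for i in range(n_taxa):
            for j in range(n_real):
                v = cm.states[i][j]
                if v is MISSING:
                    tip[i, : ks[j], j] = 1.0
                else:
                    if v >= ks[j]:
                        raise ValueError(
                            f"state {v} exceeds state count {ks[j]} for "
                            f"character {cm.characters[j]}"
                        )
                    tip[i, v, j] = 1.0
            for a, k in enumerate(aug_ks):
                tip[i, 0, n_real + a] = 1.0  # constant all-zero pattern
        kf = all_ks / (all_ks - 1.0)
        return cls(
            tuple(cm.taxa), n_real, all_ks, tip, mask, kf, 1.0 / all_ks,
            const_of_k, settings.variable_coding,
        )


@njit(cache=True)
def _mk_prune_kernel(post, cptr, cidx, blen, tip, mask, kfac, inv_k):
    n_nodes = cptr.shape[0] - 1
    n_leaves, ns, s_tot = tip.shape
    part = np.zeros((n_nodes, ns, s_tot))
    for v in range(n_leaves):
        part[v] = tip[v]
    for ii in range(post.shape[0]):
        v = post[ii]
        if v < n_leaves:
            continue
        for st in range(ns):
            for s in range(s_tot):
                part[v, st, s] = mask[st, s]
        for ci in range(cptr[v], cptr[v + 1]):
            c = cidx[ci]
            t = blen[c]
            for s in range(s_tot):
                e = math.exp(-kfac[s] * t)
                pd = (1.0 - e) * inv_k[s]
                tot = 0.0
                for st in range(ns):
                    tot += part[c, st, s]
                base = pd * tot
                for st in range(ns):
                    part[v, st, s] *= base + e * part[c, st, s]
    root = post[post.shape[0] - 1]
    out = np.empty(s_tot)
    for s in range(s_tot):
        tot = 0.0
        for st in range(ns):
            tot += part[root, st, s]
        tot *= inv_k[s]
        out[s] = math.log(tot) if tot > 0 else -np.inf
    return out


def _mk_prune_numpy(post, cptr, cidx, blen, tip, mask, kfac, inv_k):
    """Vectorised reference implementation of the Mk pruning kernel."""
    n_nodes = cptr.shape[0] - 1
    n_leaves = tip.shape[0]
    part = np.zeros((n_nodes,) + tip.shape[1:])
    part[:n_leaves] = tip
    for v in post:
        v = int(v)
        if v < n_leaves:
            continue
        acc = mask.copy()
        for c in cidx[cptr[v]:cptr[v + 1]]:
            e = np.exp(-kfac * blen[c])
            pd = (1.0 - e) * inv_k
            tot = part[c].sum(axis=0)
            acc = acc * (pd * tot + e * part[c])
        part[v] = acc
    root = int(post[-1])
    with np.errstate(divide="ignore"):
        return np.log(part[root].sum(axis=0) * inv_k)


def mk_site_log_likelihoods(
    tree: Tree, data: CharacterData, use_numba: bool = True
) -> np.ndarray:
    """Per-site log likelihoods (including any augmented constant sites)."""
    if tuple(tree.taxa) != data.taxa:
        raise ValueError("tree and character data taxa disagree")
    post = tree.postorder()
    cptr, cidx = tree.flat_children()
    kernel = _mk_prune_kernel if (use_numba and _HAVE_NUMBA) else _mk_prune_numpy
    return kernel(post, cptr, cidx, tree.blen, data.tip, data.mask,
                  data.kfac, data.inv_k)


def mk_log_likelihood(tree: Tree, data: CharacterData) -> float:
    """Plain Mk log likelihood (no variable-coding correction)."""
    site = mk_site_log_likelihoods(tree, data)
    return float(site[: data.n_sites].sum())


def mkv_corrected_log_likelihood(tree: Tree, data: CharacterData) -> float:
    """Mkv log likelihood: per character, condition on being variable."""
    if not data.variable_coding:
        raise ValueError("character data was prepared without variable coding")
    site = mk_site_log_likelihoods(tree, data)
    total = 0.0
    for s in range(data.n_sites):
        k = int(data.k[s])
        log_const = site[data.const_site_of_k[k]]
        p_const = k * math.exp(log_const)
        if p_const >= 1.0:
            return -math.inf  # zero-length tree: no variable pattern possible
        total += site[s] - math.log1p(-p_const)
    return float(total)


def mk_edge_factors(blen: np.ndarray, kfac: np.ndarray, inv_k: np.ndarray):
    """Closed-form per-edge, per-site factors (e, pd) with
    P(same) = pd + e and P(any specific different state) = pd."""
    e = np.exp(-np.multiply.outer(blen, kfac))  # (nodes, S)
    pd = (1.0 - e) * inv_k[None, :]
    return e, pd


def mk_inside_outside(tree: Tree, data: CharacterData):
    """Inside/outside partial likelihoods for the symmetric Mk model.

    Returns ``(inside, outside)``:

    * ``inside[v]`` is the likelihood of the data in the subtree below
      node ``v`` given the state at ``v`` (before ``v``'s own edge);
    * ``outside[v]`` is the likelihood of everything outside ``v``'s
      subtree as a function of the state at ``v``'s *parent*, including
      the 1/k stationary factor.

    For any node ``v`` with parent edge length ``t``,
    ``sum_s outside[v][s] * (message of inside[v] through t)[s]`` is the
    per-site likelihood; this identity is what informed reattachment
    proposals exploit.
    """
    if tuple(tree.taxa) != data.taxa:
        raise ValueError("tree and character data taxa disagree")
    n_nodes = tree.n_nodes
    n_leaves = tree.n_leaves
    post = tree.postorder()
    e, pd = mk_edge_factors(tree.blen, data.kfac, data.inv_k)
    shape = data.tip.shape[1:]
    inside = np.zeros((n_nodes,) + shape)
    message = np.zeros((n_nodes,) + shape)  # inside propagated through edge
    inside[:n_leaves] = data.tip
    for v in post:
        v = int(v)
        if v >= n_leaves:
            acc = data.mask.copy()
            for c in tree.children[v]:
                acc = acc * message[c]
            inside[v] = acc
        if v != tree.root:
            tot = inside[v].sum(axis=0)
            message[v] = (pd[v] * tot[None, :] + e[v] * inside[v]) * data.mask
    outside = np.zeros((n_nodes,) + shape)
    for v in post[::-1]:  # top-down
        v = int(v)
        if tree.is_leaf(v) and v != tree.root:
            continue
        if v == tree.root:
            beyond = data.inv_k[None, :] * data.mask
        else:
            o = outside[v]
            tot = o.sum(axis=0)
            beyond = (pd[v] * tot[None, :] + e[v] * o) * data.mask
        for c in tree.children[v]:
            sib = beyond
            for c2 in tree.children[v]:
                if c2 != c:
                    sib = sib * message[c2]
            outside[c] = sib
    return inside, outside


def mk_subtree_inside(tree: Tree, data: CharacterData, x: int) -> np.ndarray:
    """Inside partial likelihood at node ``x`` from its own subtree only."""
    if tuple(tree.taxa) != data.taxa:
        raise ValueError("tree and character data taxa disagree")
    if tree.is_leaf(x):
        return data.tip[x]
    e, pd = mk_edge_factors(tree.blen, data.kfac, data.inv_k)
    order: list[int] = []
    stack = [x]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(tree.children[v])
    inside: dict[int, np.ndarray] = {}
    for v in order[::-1]:
        if tree.is_leaf(v):
            inside[v] = data.tip[v]
            continue
        acc = data.mask.copy()
        for c in tree.children[v]:
            ins = inside[c]
            tot = ins.sum(axis=0)
            acc = acc * (pd[c] * tot[None, :] + e[c] * ins)
        inside[v] = acc
    return inside[x]


def mk_reattachment_log_likelihoods(
    tree: Tree,
    data: CharacterData,
    pendant_inside: np.ndarray,
    candidates,
    pendant_length: float,
):
    """Log likelihood of attaching a pendant subtree to the midpoint of
    each candidate edge of a reduced tree (the subtree already pruned).

    ``tree`` must be the reduced tree (the pruned nodes may still exist as
    ids but must be disconnected); ``pendant_inside`` is the inside partial
    at the pendant subtree's root (a tip partial when pruning a leaf).
    Returns an array of total log likelihoods, one per candidate, with the
    variable-coding correction applied when the data carry it.
    """
    inside, outside = mk_inside_outside(tree, data)
    tipx = pendant_inside
    ex, pdx = mk_edge_factors(np.array([pendant_length]), data.kfac,
                              data.inv_k)
    mx = (pdx[0] * tipx.sum(axis=0)[None, :] + ex[0] * tipx) * data.mask

    cand = np.asarray(candidates, dtype=np.int64)
    eh, pdh = mk_edge_factors(tree.blen[cand] / 2.0, data.kfac, data.inv_k)
    eh = eh[:, None, :]  # (C, 1, S)
    pdh = pdh[:, None, :]
    ins = inside[cand]  # (C, states, S)
    out_ = outside[cand]
    m_low = pdh * ins.sum(axis=1, keepdims=True) + eh * ins
    o_up = pdh * out_.sum(axis=1, keepdims=True) + eh * out_
    # the shared mask zeroes padded states once; (mask applied to mx)
    site = (o_up * m_low * mx[None]).sum(axis=1)  # (C, S)
    with np.errstate(divide="ignore"):
        logs = np.log(site)
    totals = logs[:, : data.n_sites].sum(axis=1)
    if data.variable_coding:
        ks = data.k[: data.n_sites]
        for k, const_idx in data.const_site_of_k.items():
            n_k = int((ks == k).sum())
            if n_k == 0:
                continue
            p_const = k * np.exp(logs[:, const_idx])
            bad = p_const >= 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = -n_k * np.log1p(-np.where(bad, 0.0, p_const))
            totals = np.where(bad, -np.inf, totals + corr)
    return totals


@njit(cache=True)
def _mk_reattach_kernel(post, cptr, cidx, blen, tip, mask, kfac, inv_k,
                        n_leaves, root, cand, pendant_msg,
                        n_sites, kvec, const_counts):
    n_nodes = cptr.shape[0] - 1
    ns = tip.shape[1]
    s_tot = tip.shape[2]
    inside = np.zeros((n_nodes, ns, s_tot))
    message = np.zeros((n_nodes, ns, s_tot))
    for v in range(n_leaves):
        inside[v] = tip[v]
    for ii in range(post.shape[0]):
        v = post[ii]
        if v >= n_leaves:
            for st in range(ns):
                for s in range(s_tot):
                    inside[v, st, s] = mask[st, s]
            for ci in range(cptr[v], cptr[v + 1]):
                c = cidx[ci]
                for st in range(ns):
                    for s in range(s_tot):
                        inside[v, st, s] *= message[c, st, s]
        if v != root:
            t = blen[v]
            for s in range(s_tot):
                e = math.exp(-kfac[s] * t)
                pd = (1.0 - e) * inv_k[s]
                tot = 0.0
                for st in range(ns):
                    tot += inside[v, st, s]
                for st in range(ns):
                    message[v, st, s] = (pd * tot + e * inside[v, st, s]) \
                        * mask[st, s]
    outside = np.zeros((n_nodes, ns, s_tot))
    beyond = np.empty((ns, s_tot))
    for ii in range(post.shape[0] - 1, -1, -1):
        v = post[ii]
        if cptr[v + 1] == cptr[v]:
            continue
        if v == root:
            for st in range(ns):
                for s in range(s_tot):
                    beyond[st, s] = inv_k[s] * mask[st, s]
        else:
            t = blen[v]
            for s in range(s_tot):
                e = math.exp(-kfac[s] * t)
                pd = (1.0 - e) * inv_k[s]
                tot = 0.0
                for st in range(ns):
                    tot += outside[v, st, s]
                for st in range(ns):
                    beyond[st, s] = (pd * tot + e * outside[v, st, s]) \
                        * mask[st, s]
        for ci in range(cptr[v], cptr[v + 1]):
            c = cidx[ci]
            for st in range(ns):
                for s in range(s_tot):
                    outside[c, st, s] = beyond[st, s]
            for cj in range(cptr[v], cptr[v + 1]):
                c2 = cidx[cj]
                if c2 == c:
                    continue
                for st in range(ns):
                    for s in range(s_tot):
                        outside[c, st, s] *= message[c2, st, s]
    totals = np.empty(cand.shape[0])
    for idx in range(cand.shape[0]):
        v = cand[idx]
        half = blen[v] / 2.0
        total = 0.0
        ok = True
        for s in range(s_tot):
            e = math.exp(-kfac[s] * half)
            pd = (1.0 - e) * inv_k[s]
            tot_i = 0.0
            tot_o = 0.0
            for st in range(ns):
                tot_i += inside[v, st, s]
                tot_o += outside[v, st, s]
            site = 0.0
            for st in range(ns):
                m_low = pd * tot_i + e * inside[v, st, s]
                o_up = pd * tot_o + e * outside[v, st, s]
                site += o_up * m_low * pendant_msg[st, s] * mask[st, s]
            if s < n_sites:
                if site <= 0.0:
                    ok = False
                    break
                total += math.log(site)
            else:
                p_const = kvec[s] * site
                if p_const >= 1.0:
                    ok = False
                    break
                total -= const_counts[s - n_sites] * math.log1p(-p_const)
        totals[idx] = total if ok else -np.inf
    return totals


def mk_reattachment_log_likelihoods_fast(
    tree: Tree,
    data: CharacterData,
    pendant_inside: np.ndarray,
    candidates,
    pendant_length: float,
):
    """JIT path of :func:`mk_reattachment_log_likelihoods` (same contract)."""
    if not _HAVE_NUMBA:
        return mk_reattachment_log_likelihoods(tree, data, pendant_inside,
                                               candidates, pendant_length)
    post = tree.postorder()
    cptr, cidx = tree.flat_children()
    tipx = pendant_inside
    ex, pdx = mk_edge_factors(np.array([pendant_length]), data.kfac,
                              data.inv_k)
    mx = (pdx[0] * tipx.sum(axis=0)[None, :] + ex[0] * tipx) * data.mask
    ks = data.k[: data.n_sites]
    const_counts = np.array(
        [float((ks == k).sum()) for k in data.k[data.n_sites:]])
    return _mk_reattach_kernel(
        post, cptr, cidx, tree.blen, data.tip, data.mask, data.kfac,
        data.inv_k, tree.n_leaves, tree.root,
        np.asarray(candidates, dtype=np.int64), mx,
        data.n_sites, data.k.astype(np.float64), const_counts,
    )


def character_data_from_matrix(
    cm: CharacterMatrix,
    settings: MkSettings | None = None,
    state_counts: Sequence[int] | None = None,
) -> CharacterData:
    return CharacterData.from_matrix(cm, settings, state_counts)
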