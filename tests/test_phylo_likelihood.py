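"""Substitution models and pruning likelihoods against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from vrdphylo.data_io import CharacterMatrix
from vrdphylo.phylo_engine import (
    MkSettings,
    RateHeterogeneity,
    SubstitutionModel,
    Tree,
    character_data_from_matrix,
    mk_log_likelihood,
    mk_site_log_likelihoods,
    mkv_corrected_log_likelihood,
    transition_matrix,
    tree_log_likelihood,
)


def brute_force_loglik(tree, data, model, het=None):
    """Exhaustive enumeration over internal-node state assignments."""
    n = model.n_states
    pi = model.stationary_frequencies
    if het is None:
        rates, weights, p_inv = [1.0], [1.0], 0.0
    else:
        r, w = het.mixture_rates()
        rates, weights, p_inv = list(r), list(w), het.p_invariant
    taxa = tree.taxa
    n_leaves = len(taxa)
    lookup = {c: i for i, c in enumerate(model.alphabet)}
    length = len(next(iter(data.values())))
    internal = [v for v in range(tree.n_nodes) if v >= n_leaves]
    total = 0.0
    for s in range(length):
        tips = {i: lookup.get(data[taxa[i]][s], -1) for i in range(n_leaves)}
        site = 0.0
        for rate, wt in zip(rates, weights):
            mats = {v: transition_matrix(model, float(tree.blen[v]), rate)
                    for v in range(tree.n_nodes) if v != tree.root}
            lik = 0.0
            for assign in itertools.product(range(n), repeat=len(internal)):
                amap = dict(zip(internal, assign))
                p = pi[amap[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    ps = amap[int(tree.parent[v])]
                    if v < n_leaves:
                        p *= 1.0 if tips[v] == -1 else mats[v][ps, tips[v]]
                    else:
                        p *= mats[v][ps, amap[v]]
                lik += p
            site += wt * lik
        if p_inv > 0:
            site += p_inv * sum(
                pi[i] for i in range(n)
                if all(tips[l] in (-1, i) for l in range(n_leaves))
            )
        total += math.log(site)
    return total


def random_tree(rng, n_taxa, scale=0.3):
    blens = rng.exponential(scale, size=2 * n_taxa - 2)
    t = Tree.random_topology([f"t{i}" for i in range(n_taxa)], rng,
                             branch_lengths=blens)
    t.blen[t.root] = 0.0
    return t


class TestTransitionMatrix:
    def test_zero_length_is_identity(self):
        m = SubstitutionModel.mk(4, alphabet="ACGT")
        np.testing.assert_allclose(transition_matrix(m, 0.0), np.eye(4),
                                   atol=1e-14)

    def test_long_branch_reaches_stationarity(self, rng):
        freqs = rng.dirichlet(np.ones(4) * 5)
        ex = np.ones((4, 4)) + rng.random((4, 4))
        m = SubstitutionModel(4, (ex + ex.T) / 2, freqs, alphabet="ACGT")
        p = transition_matrix(m, 100.0)
        for row in p:
            np.testing.assert_allclose(row, freqs, atol=1e-6)

    def test_jukes_cantor_closed_form(self):
        m = SubstitutionModel.mk(4, alphabet="ACGT")
        for t in (0.01, 0.1, 0.5, 2.0):
            p = transition_matrix(m, t)
            p_ii = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            np.testing.assert_allclose(np.diag(p), p_ii, atol=1e-10)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_non_finite_length_rejected(self):
        m = SubstitutionModel.mk(2)
        with pytest.raises(ValueError):
            transition_matrix(m, math.nan)


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0, 50.0])
    def test_category_rates_have_mean_one(self, alpha):
        h = RateHeterogeneity(alpha, 4, 0.0)
        assert h.category_rates().mean() == pytest.approx(1.0, abs=1e-10)

    def test_mixture_mean_one_with_invariant_class(self):
        h = RateHeterogeneity(0.5, 4, 0.3)
        rates, weights = h.mixture_rates()
        assert (rates * weights).sum() == pytest.approx(1.0, abs=1e-10)

    def test_homogeneous_limit(self, rng):
        """alpha -> infinity with p_inv = 0 reduces to the uniform-rate
        model."""
        tree = random_tree(rng, 5)
        model = SubstitutionModel.mk(4, alphabet="ACGT")
        data = {t: "".join(rng.choice(list("ACGT"), size=30))
                for t in tree.taxa}
        flat = tree_log_likelihood(tree, data, model, None)
        near = tree_log_likelihood(
            tree, data, model, RateHeterogeneity(1e13, 4, 0.0))
        assert near == pytest.approx(flat, abs=1e-8)


class TestPruningOracle:
    def test_matches_enumeration_on_small_trees(self, rng):
        """Pruning equals exhaustive enumeration on all <=5-taxon,
        <=4-state cases sampled across shapes, alphabets and rate models."""
        for trial in range(8):
            n_taxa = 3 + trial % 3  # 3..5
            n_states = 2 + trial % 3  # 2..4
            tree = random_tree(rng, n_taxa)
            alphabet = "ACGT"[:n_states]
            freqs = rng.dirichlet(np.ones(n_states) * 5)
            ex = np.ones((n_states, n_states)) + rng.random(
                (n_states, n_states))
            model = SubstitutionModel(n_states, (ex + ex.T) / 2, freqs,
                                      alphabet=alphabet)
            data = {t: "".join(rng.choice(list(alphabet + "-?"), size=4))
                    for t in tree.taxa}
            het = (RateHeterogeneity(0.7, 3, 0.25) if trial % 2 else None)
            fast = tree_log_likelihood(tree, data, model, het)
            slow = brute_force_loglik(tree, data, model, het)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_rerooting_invariance(self, rng):
        tree = random_tree(rng, 6)
        model = SubstitutionModel.mk(4, alphabet="ACGT")
        data = {t: "".join(rng.choice(list("ACGT"), size=15))
                for t in tree.taxa}
        base = tree_log_likelihood(tree, data, model)
        for v in range(tree.n_leaves, tree.n_nodes):
            if v == tree.root:
                continue
            assert tree_log_likelihood(tree.rerooted(v), data, model) == \
                pytest.approx(base, abs=1e-9)

    def test_child_order_invariance(self, rng):
        tree = random_tree(rng, 6)
        model = SubstitutionModel.mk(3, alphabet="012")
        data = {t: "".join(rng.choice(list("012"), size=10))
                for t in tree.taxa}
        base = tree_log_likelihood(tree, data, model)
        for v in range(tree.n_leaves, tree.n_nodes):
            tree.children[v] = tree.children[v][::-1]
        tree.invalidate()
        assert tree_log_likelihood(tree, data, model) == \
            pytest.approx(base, abs=1e-12)

    def test_all_sites_invariant_with_variable_column(self, rng):
        tree = random_tree(rng, 4)
        model = SubstitutionModel.mk(4, alphabet="ACGT")
        data = {t: "A" for t in tree.taxa}
        data[tree.taxa[0]] = "C"
        lnl = tree_log_likelihood(tree, data, model,
                                  RateHeterogeneity(1.0, 4, 1.0))
        assert lnl == -math.inf


def _star3(taxa, b0, b1):
    # two informative leaves plus one fully ambiguous leaf: effectively a
    # two-taxon tree with path length b0 + b1
    return Tree(taxa, [3, 3, 3, -1], [[], [], [], [0, 1, 2]],
                [b0, b1, 0.0, 0.0], 3)


class TestMkLikelihood:
    def test_two_taxon_identical_state_closed_form(self):
        taxa = ("a", "b", "c")
        for k, v in [(2, 0.7), (3, 0.7), (4, 1.3)]:
            tree = _star3(taxa, 0.3, v - 0.3)
            cm = CharacterMatrix(taxa, ("c1",), ((0,), (0,), (None,)))
            cd = character_data_from_matrix(cm, MkSettings(False),
                                            state_counts=[k])
            got = mk_log_likelihood(tree, cd)
            expect = math.log(
                (1 / k) * (1 / k + (k - 1) / k * math.exp(-k * v / (k - 1))))
            assert got == pytest.approx(expect, abs=1e-12)

    def test_kernel_matches_generic_route(self, rng):
        """The closed-form symmetric kernel agrees with the dense
        eigendecomposition route for every state count."""
        tree = random_tree(rng, 6)
        ks = [2, 3, 4, 2, 3]
        states = tuple(
            tuple(None if rng.random() < 0.2 else int(rng.integers(k))
                  for k in ks)
            for _ in range(6)
        )
        cm = CharacterMatrix(tree.taxa, tuple(f"c{j}" for j in range(5)),
                             states)
        cd = character_data_from_matrix(cm, MkSettings(False),
                                        state_counts=ks)
        site = mk_site_log_likelihoods(tree, cd, use_numba=False)
        site_nb = mk_site_log_likelihoods(tree, cd, use_numba=True)
        np.testing.assert_allclose(site, site_nb, atol=1e-12)
        for j, k in enumerate(ks):
            model = SubstitutionModel.mk(k)
            data = {
                t: "?" if states[i][j] is None else str(states[i][j])
                for i, t in enumerate(tree.taxa)
            }
            assert tree_log_likelihood(tree, data, model) == \
                pytest.approx(site[j], abs=1e-10)

    def test_mkv_two_taxon_algebra(self):
        """Conditional (variable-coded) likelihood matches the transition
        probability algebra on the smallest tree."""
        taxa = ("a", "b", "c")
        b0, b1 = 0.2, 0.3
        tree = _star3(taxa, b0, b1)
        cm = CharacterMatrix(taxa, ("c1",), ((0,), (1,), (None,)))
        cd = character_data_from_matrix(cm, MkSettings(True),
                                        state_counts=[2])
        got = mkv_corrected_log_likelihood(tree, cd)
        p_same = lambda t: 0.5 + 0.5 * math.exp(-2 * t)
        joint = 0.25 * (1 - math.exp(-2 * (b0 + b1)))
        # the conditioning denominator spans all three taxa, the ambiguous
        # one contributing its zero-length branch deterministically
        p_const = p_same(b0) * p_same(b1)
        assert got == pytest.approx(math.log(joint / (1 - p_const)),
                                    abs=1e-12)

    def test_mkv_matches_enumeration_on_four_taxa(self, rng):
        tree = random_tree(rng, 4)
        states = ((0, 1), (1, 0), (0, 0), (1, 2))
        cm = CharacterMatrix(tree.taxa, ("c1", "c2"), states)
        cd = character_data_from_matrix(cm, MkSettings(True),
                                        state_counts=[2, 3])
        got = mkv_corrected_log_likelihood(tree, cd)
        expect = 0.0
        for j, k in enumerate(cd.k[: cd.n_sites]):
            k = int(k)
            model = SubstitutionModel.mk(k)
            data = {t: str(states[i][j]) for i, t in enumerate(tree.taxa)}
            raw = brute_force_loglik(tree, data, model)
            const = sum(
                math.exp(brute_force_loglik(
                    tree, {t: str(s) for t in tree.taxa}, model))
                for s in range(k)
            )
            expect += raw - math.log(1 - const)
        assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("n_taxa", [4, 8, 16])
    def test_correction_reaches_long_branch_limit(self, rng, n_taxa):
        """On saturated branches the constant-pattern probability tends to
        k^(1-L), so the variable-coding correction approaches the analytic
        limit -log(1 - k^(1-L)) and vanishes as the taxon count grows."""
        tree = random_tree(rng, n_taxa)
        tree.blen[:] = 50.0
        tree.blen[tree.root] = 0.0
        states = tuple((i % 2,) for i in range(n_taxa))
        cm = CharacterMatrix(tree.taxa, ("c1",), states)
        cd_v = character_data_from_matrix(cm, MkSettings(True),
                                          state_counts=[2])
        cd_p = character_data_from_matrix(cm, MkSettings(False),
                                          state_counts=[2])
        corrected = mkv_corrected_log_likelihood(tree, cd_v)
        plain = mk_log_likelihood(tree, cd_p)
        limit = -math.log(1.0 - 2.0 ** (1 - n_taxa))
        assert corrected - plain == pytest.approx(limit, abs=1e-9)
        assert limit < 0.1 if n_taxa >= 8 else limit > 0.1

    def test_constant_character_rejected_under_variable_coding(self):
        cm = CharacterMatrix(("a", "b", "c"), ("c1",), ((1,), (1,), (1,)))
        with pytest.raises(ValueError, match="constant"):
            character_data_from_matrix(cm, MkSettings(True))

    @pytest.mark.parametrize("variable_coding", [True, False])
    def test_reattachment_scores_match_direct_evaluation(self, variable_coding):
        """Inside/outside attachment scoring equals pruning the tree with
        the leaf actually attached, for every candidate edge."""
        from vrdphylo.phylo_engine.likelihood import (
            mk_reattachment_log_likelihoods,
            mk_reattachment_log_likelihoods_fast,
            mk_subtree_inside,
        )
        from vrdphylo.synthetic_data import simulate_characters, simulate_tree

        tree = simulate_tree(7, seed=9, scale=0.4)
        cm, _ = simulate_characters(tree, state_counts=[2, 2, 3, 4, 2, 3],
                                    seed=3, reject_constant=True)
        cd = character_data_from_matrix(cm, MkSettings(variable_coding))
        t = tree.copy()
        x = 3
        p = int(t.parent[x])
        g = int(t.parent[p])
        s = [c for c in t.children[p] if c != x][0]
        t.children[g][t.children[g].index(p)] = s
        t.parent[s] = g
        t.blen[s] = t.blen[s] + t.blen[p]
        t.invalidate()
        cands = [v for v in range(t.n_nodes)
                 if v != t.root and v != x and v != p]
        pendant = mk_subtree_inside(t, cd, x)
        scores = mk_reattachment_log_likelihoods(t, cd, pendant, cands,
                                                 t.blen[x])
        fast = mk_reattachment_log_likelihoods_fast(t, cd, pendant, cands,
                                                    t.blen[x])
        np.testing.assert_allclose(scores, fast, atol=1e-10)
        for idx, e in enumerate(cands):
            pe = int(t.parent[e])
            full = t.blen[e]
            t.children[pe][t.children[pe].index(e)] = p
            t.parent[p] = pe
            t.children[p] = [e, x]
            t.parent[e] = p
            t.parent[x] = p
            t.blen[p] = full / 2
            t.blen[e] = full / 2
            t.invalidate()
            direct = (mkv_corrected_log_likelihood(t, cd) if variable_coding
                      else mk_log_likelihood(t, cd))
            assert scores[idx] == pytest.approx(direct, abs=1e-9)
            t.children[pe][t.children[pe].index(p)] = e
            t.parent[e] = pe
            t.blen[e] = full
            t.invalidate()

    def test_zero_length_tree_has_no_variable_pattern(self):
        taxa = ("a", "b", "c")
        tree = _star3(taxa, 0.0, 0.0)
        cm = CharacterMatrix(taxa, ("c1",), ((0,), (1,), (None,)))
        cd = character_data_from_matrix(cm, MkSettings(True),
                                        state_counts=[2])
        assert mkv_corrected_log_likelihood(tree, cd) == -math.inf
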