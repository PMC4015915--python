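"""Superposition, correspondence, homomorph RMSD and secondary structure."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from vrdphylo.struct_compare import (
    ResidueCorrespondence,
    SegmentAnnotation,
    StructureError,
    StructureModel,
    assign_sse,
    detect_permutation,
    homomorph_rmsd_table,
    iterative_superpose,
    kabsch_superpose,
    match_residues,
    parse_structure,
    segment_rmsd,
    write_pdb,
)
from vrdphylo.synthetic_data import perturb_structure, simulate_structure

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       2.000   1.500   0.000  1.00  0.00           C
ATOM      4  CA BSER A   3       3.000   3.000   0.500  1.00  0.00           C
ATOM      5  CA CSER A   3       9.000   9.000   9.500  1.00  0.00           C
ATOM      6  CA  LEU B  10       0.000   0.000   9.000  1.00  0.00           C
END
"""


def _model(coords, label="m", segments=()):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(label, tuple(range(1, n + 1)), "A" * n, coords,
                          tuple(segments))


class TestParseStructure:
    def test_three_residue_chain(self):
        m = parse_structure(PDB_3RES, "A")
        assert len(m) == 3
        assert m.sequence == "AGS"
        assert m.residue_numbers == (1, 2, 3)

    def test_first_altloc_occurrence_wins(self):
        m = parse_structure(PDB_3RES, "A")
        np.testing.assert_allclose(m.coords[2], [3.0, 3.0, 0.5])

    def test_absent_chain_is_an_error(self):
        with pytest.raises(StructureError, match="chain 'Z'"):
            parse_structure(PDB_3RES, "Z")

    def test_chain_without_ca_is_an_error(self):
        text = "ATOM      1  N   ALA A   1       0.0     0.0     0.0  " \
               "1.00  0.00           N\nEND\n"
        with pytest.raises(StructureError, match="no C"):
            parse_structure(text, "A")

    def test_pdb_write_parse_round_trip(self):
        s = simulate_structure("HHHHHHHHLLL", seed=3)
        back = parse_structure(write_pdb(s), "A")
        np.testing.assert_allclose(back.coords, np.round(s.coords, 3),
                                   atol=1e-6)
        assert back.residue_numbers == s.residue_numbers


class TestKabsch:
    def test_identical_points(self, rng):
        pts = rng.normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_rigid_transform(self, rng):
        pts = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(sup.translation, [5, 0, 0], atol=1e-9)

    def test_matches_numerical_optimiser_on_noisy_points(self, rng):
        """The SVD solution attains the global minimum over rotations."""
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=(10, 3))
        sup = kabsch_superpose(a, b)

        def objective(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            moved = a @ rot.T
            moved = moved - moved.mean(0) + b.mean(0)
            return np.sqrt(((moved - b) ** 2).sum() / len(a))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [np.zeros(3), np.array([1.0, 0.5, -0.5]),
                       np.array([-2.0, 1.0, 2.0])]
        )
        assert sup.rmsd == pytest.approx(best, abs=1e-6)

    def test_rigid_invariance_and_proper_rotation(self, rng):
        """Common rigid motions leave the RMSD unchanged; det(R) = +1
        even for mirror-image inputs."""
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(scale=0.5, size=(12, 3))
        base = kabsch_superpose(a, b).rmsd
        for _ in range(5):
            rot = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31)))).as_matrix()
            shift = rng.normal(scale=10, size=3)
            sup = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)
            assert sup.rmsd == pytest.approx(base, abs=1e-9)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        mirrored = b.copy()
        mirrored[:, 2] *= -1
        sup = kabsch_superpose(a, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(StructureError, match="collinear"):
            kabsch_superpose(line, line)


class TestMatchResidues:
    def test_identical_structures_fully_paired(self, rng):
        s = _model(rng.normal(size=(20, 3)) * 4)
        sup = kabsch_superpose(s.coords, s.coords)
        corr = match_residues(s, s, sup, cutoff=4.0)
        assert corr.pairs == tuple((i, i) for i in range(20))

    def test_no_atoms_within_cutoff(self, rng):
        a = _model(rng.normal(size=(5, 3)))
        b = _model(rng.normal(size=(5, 3)) + 100.0)
        sup = kabsch_superpose(np.eye(3), np.eye(3))
        assert len(match_residues(a, b, sup, cutoff=1.0)) == 0

    def test_matches_lis_oracle_on_crossing_pattern(self):
        """Mutual nearest neighbours that cross in sequence are reduced to
        the longest order-preserving subset (exhaustive oracle)."""
        a = _model([[0, 0, 0], [1, 0.7, 0], [2, 0, 0], [3, 0.7, 0],
                    [4, 0, 0.3]])
        # b's residues are a's in shuffled order: mutual NN pairs cross
        perm = [0, 2, 1, 4, 3]
        b = _model(a.coords[perm])
        sup = kabsch_superpose(a.coords, a.coords)  # identity frame
        corr = match_residues(a, b, sup, cutoff=0.5)
        candidates = [(i, perm.index(i)) for i in range(5)]
        best = max(
            (
                sub
                for r in range(6)
                for sub in itertools.combinations(candidates, r)
                if all(x2 > x1 and y2 > y1 for (x1, y1), (x2, y2)
                       in zip(sub, sub[1:]))
            ),
            key=len,
        )
        assert len(corr) == len(best)
        assert all(j2 > j1 for (_, j1), (_, j2)
                   in zip(corr.pairs, corr.pairs[1:]))

    def test_order_violation_rejected_at_construction(self):
        with pytest.raises(StructureError):
            ResidueCorrespondence(((0, 1), (1, 0)))


class TestIterativeSuperpose:
    def test_rigid_copy_from_three_pair_seed(self, rng):
        s = simulate_structure("LLHHHHHHHHHHHHLLEEEEEELL", seed=1)
        moved, truth = perturb_structure(
            s, translation=np.array([3.0, -2.0, 1.0]), seed=2)
        seed_corr = ResidueCorrespondence(((0, 0), (5, 5), (20, 20)))
        sup, corr = iterative_superpose(s, moved, seed_corr)
        assert len(corr) == len(s)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, truth.rotation, atol=1e-8)

    def test_converged_input_is_fixed_point(self, rng):
        s = _model(rng.normal(size=(15, 3)) * 5)
        full = ResidueCorrespondence(tuple((i, i) for i in range(15)))
        trace = []
        sup, corr = iterative_superpose(s, s, full, trace=trace)
        assert corr.pairs == full.pairs
        assert len(trace) == 2  # seed evaluation + single confirming pass

    def test_noisy_copy_close_to_known_correspondence_oracle(self):
        s = simulate_structure("H" * 60, seed=5)
        noisy, _ = perturb_structure(s, rotation=np.eye(3), noise_sigma=0.5,
                                     seed=6)
        oracle = kabsch_superpose(s.coords, noisy.coords).rmsd
        seed_corr = ResidueCorrespondence(((0, 0), (1, 1), (2, 2), (3, 3)))
        sup, corr = iterative_superpose(s, noisy, seed_corr)
        assert sup.rmsd <= oracle * 1.1
        assert len(corr) >= 0.9 * len(s)

    def test_rmsd_trace_non_increasing_at_stable_size(self):
        s = simulate_structure("H" * 40 + "L" * 10, seed=9)
        noisy, _ = perturb_structure(s, rotation=np.eye(3), noise_sigma=0.4,
                                     seed=10)
        trace = []
        iterative_superpose(
            s, noisy, ResidueCorrespondence(((0, 0), (10, 10), (20, 20))),
            trace=trace)
        by_size = {}
        for n, r in trace:
            by_size.setdefault(n, []).append(r)
        for rmsds in by_size.values():
            assert all(b <= a + 1e-12 for a, b in zip(rmsds, rmsds[1:]))

    def test_small_seed_is_an_error(self, rng):
        s = _model(rng.normal(size=(6, 3)))
        with pytest.raises(StructureError):
            iterative_superpose(s, s, ResidueCorrespondence(((0, 0), (1, 1))))


class TestSegmentRmsd:
    def _segmented(self, rng, hm="hmH", n=30, lo=5, hi=10):
        s = _model(rng.normal(size=(n, 3)) * 5,
                   segments=[SegmentAnnotation(hm, lo, hi)])
        return s

    def test_identical_segments_zero(self, rng):
        s = self._segmented(rng)
        seg = s.segment("hmH")
        assert segment_rmsd(s, s, seg, seg) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero_in_local_frame(self, rng):
        s = self._segmented(rng)
        moved, _ = perturb_structure(s, translation=np.array([1.0, 2, 3]),
                                     seed=4)
        seg = s.segment("hmH")
        assert segment_rmsd(s, moved, seg, seg) == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_global_frame_uses_supplied_superposition(self, rng):
        s = self._segmented(rng)
        moved, _ = perturb_structure(s, translation=np.array([0.0, 0, 2]),
                                     seed=4)
        sup = kabsch_superpose(s.coords, moved.coords)
        seg = s.segment("hmH")
        r = segment_rmsd(s, moved, seg, seg, frame="global",
                         superposition=sup)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_six_residue_rmsd(self):
        # one residue displaced by 0.6 A: in a fixed (identity) frame the
        # RMSD is exactly 0.6/sqrt(6); local refitting can only reduce it
        base = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                         [7.6, 3.8, 0], [3.8, 3.8, 0], [0, 3.8, 0]],
                        dtype=float)
        shifted = base.copy()
        shifted[2, 2] += 0.6
        seg = SegmentAnnotation("hmD", 1, 6)
        a = _model(base, segments=[seg])
        b = _model(shifted, segments=[seg])
        identity = kabsch_superpose(base, base)
        direct = segment_rmsd(a, b, seg, seg, frame="global",
                              superposition=identity)
        assert direct == pytest.approx(0.6 / np.sqrt(6), abs=1e-12)
        assert segment_rmsd(a, b, seg, seg) <= direct + 1e-12

    def test_unequal_lengths_error(self, rng):
        a = _model(rng.normal(size=(20, 3)),
                   segments=[SegmentAnnotation("hmD", 1, 5)])
        b = _model(rng.normal(size=(20, 3)),
                   segments=[SegmentAnnotation("hmD", 1, 8)])
        with pytest.raises(StructureError, match="length mismatch"):
            segment_rmsd(a, b, a.segment("hmD"), b.segment("hmD"))


class TestHomomorphTable:
    def _family(self, n_structs, seed0, sigma):
        base = simulate_structure("L" * 3 + "H" * 10 + "L" * 4 + "H" * 8
                                  + "L" * 3, seed=77)
        segs = [SegmentAnnotation("hmD", 4, 13),
                SegmentAnnotation("hmH", 18, 25)]
        base = base.with_segments(segs)
        out = []
        for i in range(n_structs):
            p, _ = perturb_structure(base, noise_sigma=sigma, seed=seed0 + i)
            out.append(StructureModel(f"s{i}", p.residue_numbers, p.sequence,
                                      p.coords, tuple(segs)))
        return out

    def test_symmetric_zero_diagonal(self):
        structs = self._family(3, seed0=100, sigma=0.3)
        table = homomorph_rmsd_table(structs, "hmD")
        np.testing.assert_allclose(table.values, table.values.T)
        np.testing.assert_allclose(np.diag(table.values), 0.0)

    def test_identical_structures_zero_off_diagonal(self):
        structs = self._family(2, seed0=100, sigma=0.0)
        table = homomorph_rmsd_table(structs, "hmH")
        assert table.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_table_matches_per_pair_calls(self):
        structs = self._family(3, seed0=200, sigma=0.4)
        table = homomorph_rmsd_table(structs, "hmH")
        for i in range(3):
            for j in range(i + 1, 3):
                direct = segment_rmsd(structs[i], structs[j],
                                      structs[i].segment("hmH"),
                                      structs[j].segment("hmH"))
                assert table.iloc[i, j] == pytest.approx(direct)

    def test_equal_noise_gives_comparable_motif_conservation(self):
        """Segments perturbed with the same noise level yield statistically
        indistinguishable mean RMSDs for a helix-turn-helix thumb motif and
        a similar-size established palm motif."""
        structs = self._family(6, seed0=300, sigma=0.5)
        t_hmh = homomorph_rmsd_table(structs, "hmH")
        t_hmd = homomorph_rmsd_table(structs, "hmD")
        iu = np.triu_indices(6, 1)
        mean_h = t_hmh.values[iu].mean()
        mean_d = t_hmd.values[iu].mean()
        pooled_sd = np.std(np.concatenate([t_hmh.values[iu],
                                           t_hmd.values[iu]]))
        assert abs(mean_h - mean_d) < 2 * pooled_sd

    def test_missing_annotation_leaves_nan(self, rng):
        a = _model(rng.normal(size=(10, 3)),
                   segments=[SegmentAnnotation("hmE", 1, 4)], label="a")
        b = _model(rng.normal(size=(10, 3)), label="b")
        table = homomorph_rmsd_table([a, b], "hmE")
        assert np.isnan(table.loc["a", "b"])


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        s = simulate_structure("H" * 100, seed=0)
        sse = assign_sse(s)
        interior = sse[2:-2]
        assert interior.count("H") / len(interior) >= 0.9

    def test_ideal_strand_interior(self):
        s = simulate_structure("E" * 100, seed=0)
        sse = assign_sse(s)
        interior = sse[2:-2]
        assert interior.count("E") / len(interior) >= 0.9

    def test_random_coil_mostly_loop(self):
        s = simulate_structure("L" * 200, seed=8)
        sse = assign_sse(s)
        frac = (sse.count("H") + sse.count("E")) / len(sse)
        assert frac < 0.2

    def test_rigid_motion_invariance(self):
        s = simulate_structure("LLHHHHHHHHHHLLEEEEEELLL", seed=4)
        moved, _ = perturb_structure(s, translation=np.array([4.0, 5, -6]),
                                     seed=5)
        assert assign_sse(s) == assign_sse(moved)

    def test_terminal_residues_default_loop(self):
        sse = assign_sse(simulate_structure("H" * 30, seed=2))
        assert sse[:2] == "LL" and sse[-2:] == "LL"

    def test_too_short_is_an_error(self, rng):
        with pytest.raises(StructureError):
            assign_sse(_model(rng.normal(size=(4, 3))))


class TestMotifOrder:
    def test_canonical_order(self):
        segs = [SegmentAnnotation("hmA", 10, 20),
                SegmentAnnotation("hmB", 30, 40),
                SegmentAnnotation("hmC", 50, 60)]
        assert detect_permutation(segs) == "canonical_ABC"

    def test_cyclic_permutation(self):
        segs = [SegmentAnnotation("hmC", 5, 15),
                SegmentAnnotation("hmA", 20, 30),
                SegmentAnnotation("hmB", 40, 50)]
        assert detect_permutation(segs) == "permuted_CAB"

    def test_missing_motif_indeterminate(self):
        segs = [SegmentAnnotation("hmA", 10, 20),
                SegmentAnnotation("hmC", 50, 60)]
        assert detect_permutation(segs) == "indeterminate"

    def test_other_orders_indeterminate(self):
        segs = [SegmentAnnotation("hmB", 5, 15),
                SegmentAnnotation("hmA", 20, 30),
                SegmentAnnotation("hmC", 40, 50)]
        assert detect_permutation(segs) == "indeterminate"

    def test_duplicate_motif_is_an_error(self):
        segs = [SegmentAnnotation("hmA", 10, 20),
                SegmentAnnotation("hmA", 30, 40),
                SegmentAnnotation("hmB", 45, 50),
                SegmentAnnotation("hmC", 55, 60)]
        with pytest.raises(StructureError, match="duplicated"):
            detect_permutation(segs)
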