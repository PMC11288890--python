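"""Superposition, RMSD, helix detection/axes and Cn symmetry operations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barrelforge import fixtures, geometry
from barrelforge.fixtures import ChainBuilder, CrickParams, build_ideal_helix
from barrelforge.geometry import (BackboneModel, Chain, GeometryError,
                                  HelixSegment, Transform, apply_cn,
                                  backbone_rmsd, detect_helices, fit_cn_axis,
                                  helix_axis, kabsch_superpose, read_pdb,
                                  termini_gap, write_pdb)


def _helix_model(n_res=28):
    res = build_ideal_helix("A" * n_res)
    return BackboneModel([Chain("A", res)], [HelixSegment("A", 1, n_res)])


class TestKabsch:
    def test_identical_sets_superpose_exactly(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_recovers_quarter_turn(self):
        pts = np.random.default_rng(1).normal(size=(12, 3))
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t, rmsd = kabsch_superpose(pts, pts @ rz.T)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(t.rotation, rz, atol=1e-8)

    def test_noise_recovery_is_calibrated(self):
        # per-atom rms displacement 0.5 A between two copies of a fixture
        # helix: superposed RMSD stays in [0.3, 0.7] A across 100 trials
        ca = np.array([r.atoms["CA"] for r in build_ideal_helix("A" * 28)])
        rng = np.random.default_rng(42)
        for _ in range(100):
            noisy = ca + rng.normal(0.0, 0.5 / np.sqrt(3), ca.shape)
            _, rmsd = kabsch_superpose(noisy, ca)
            assert 0.3 <= rmsd <= 0.7

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    @given(seed=st.integers(0, 500))
    def test_rmsd_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(0.0, 0.3, a.shape)
        _, r0 = kabsch_superpose(a, b)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        shift = rng.normal(0.0, 20.0, 3)
        _, r1 = kabsch_superpose(a @ R.T + shift, b)
        _, r2 = kabsch_superpose(b, a)
        assert r1 == pytest.approx(r0, abs=1e-8)
        assert r2 == pytest.approx(r0, abs=1e-8)


class TestBackboneRmsd:
    def test_self_rmsd_is_zero(self, heptamer):
        assert backbone_rmsd(heptamer, heptamer) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_copy_rmsd_is_zero(self):
        unit = _helix_model()
        model = apply_cn(unit, 7, (np.array([9.5, 0, 0]), np.array([0, 0, 1.0])))
        copy3 = BackboneModel([model.chains[3]])
        assert backbone_rmsd(unit, copy3) == pytest.approx(0.0, abs=1e-9)

    def test_empty_mapping_rejected(self, heptamer):
        with pytest.raises(GeometryError):
            backbone_rmsd(heptamer, heptamer, residue_mapping=[])

    def test_middle_turn_mapping_covers_central_residues(self, heptamer):
        mapping = geometry.middle_turn_mapping(heptamer, heptamer, n_central=7)
        assert len(mapping) == 7 * 7
        assert backbone_rmsd(heptamer, heptamer,
                             residue_mapping=mapping) == pytest.approx(0.0, abs=1e-9)


class TestHelixDetection:
    def test_ideal_helix_is_one_full_segment(self):
        model = _helix_model(28)
        segs = detect_helices(model)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1, 28)

    def test_extended_strand_yields_nothing(self):
        b = ChainBuilder()
        for _ in range(19):
            b.add_residue(130.0, -135.0)  # beta-strand torsions
        res = b.to_residues("A" * 20, psi_last=130.0)
        model = BackboneModel([Chain("A", res)])
        assert detect_helices(model) == []

    def test_hth_unit_has_three_segments(self, hth_unit_7):
        segs = detect_helices(hth_unit_7)
        assert len(segs) == 3

    def test_fixture_boundaries_recovered(self, ap_hexamer):
        segs = detect_helices(ap_hexamer)
        assert len(segs) == 6
        for seg, truth in zip(segs, ap_hexamer.helices):
            assert abs(seg.start - truth.start) <= 1
            assert abs(seg.end - truth.end) <= 1


class TestHelixAxis:
    def test_axis_matches_construction_direction(self):
        model = _helix_model()
        ax = helix_axis(model.helices[0], model)
        angle = np.degrees(np.arccos(abs(ax.direction[2])))
        assert angle < 1.0

    def test_reversing_residue_order_negates_direction(self):
        model = _helix_model()
        fwd = helix_axis(model.helices[0], model).direction
        rev_res = [r.copy() for r in reversed(model.chains[0].residues)]
        for i, r in enumerate(rev_res):
            r.number = i + 1
        rev = BackboneModel([Chain("A", rev_res)], [HelixSegment("A", 1, 28)])
        bwd = helix_axis(rev.helices[0], rev).direction
        assert np.dot(fwd, bwd) < -0.99

    def test_short_segment_rejected(self):
        model = _helix_model(28)
        with pytest.raises(GeometryError):
            helix_axis(HelixSegment("A", 1, 6), model)

    def test_axis_endpoints_stay_inside_bounding_box(self):
        # gently bent helix: axis is the best straight fit through it
        b = ChainBuilder()
        phi, psi, tau = fixtures.solve_helix_torsions(3.5, 1.51)
        rng = np.random.default_rng(3)
        for i in range(27):
            b.add_residue(psi + rng.normal(0, 3), phi + rng.normal(0, 3))
        res = b.to_residues("A" * 28, psi_last=psi)
        model = BackboneModel([Chain("A", res)], [HelixSegment("A", 1, 28)])
        ax = helix_axis(model.helices[0], model)
        ca = np.array([r.atoms["CA"] for r in res])
        lo, hi = ca.min(axis=0) - 3, ca.max(axis=0) + 3
        for p in (ax.start_point, ax.end_point):
            assert np.all(p >= lo) and np.all(p <= hi)


class TestTerminiGap:
    def test_parallel_neighbours_span_the_helix_length(self, heptamer):
        # adjacent parallel helices: C-terminus back down to N-terminus,
        # roughly the ~40 A helix length of a 28-residue helix
        gap = termini_gap(heptamer, heptamer.helices[0], heptamer.helices[1])
        assert 35.0 <= gap <= 50.0

    def test_antiparallel_neighbours_are_short_range(self, ap_hexamer):
        gap = termini_gap(ap_hexamer, ap_hexamer.helices[0], ap_hexamer.helices[1])
        assert gap < 15.0

    def test_self_gap_spans_one_helix(self, heptamer):
        gap = termini_gap(heptamer, heptamer.helices[0], heptamer.helices[0])
        length = 27 * 1.51
        assert gap == pytest.approx(length, abs=4.0)


class TestCnSymmetry:
    def test_apply_cn_multiplies_chains(self):
        unit = _helix_model()
        model = apply_cn(unit, 7, (np.array([9.5, 0, 0]), np.array([0, 0, 1.0])))
        assert len(model.chains) == 7
        assert model.n_residues == 7 * 28

    def test_apply_cn_identity_for_n1(self, heptamer):
        out = apply_cn(heptamer, 1)
        assert np.allclose(out.coords(), heptamer.coords())

    def test_copy_k_equals_rotation_by_k(self):
        unit = _helix_model()
        axis = (np.array([9.5, 0, 0]), np.array([0, 0, 1.0]))
        model = apply_cn(unit, 5, axis)
        k = 2
        t = Transform.rotation_about_axis(*axis, 2 * np.pi * k / 5)
        expected = unit.transformed(t)
        got = BackboneModel([model.chains[k]])
        assert np.allclose(got.coords(), expected.coords(), atol=1e-9)

    def test_fit_cn_axis_recovers_construction_axis(self):
        octamer = fixtures.make_barrel(CrickParams(n=8), 4)
        _, direction = fit_cn_axis(octamer, 8)
        angle = np.degrees(np.arccos(abs(direction[2])))
        assert angle < 0.5

    def test_invalid_order_rejected(self, heptamer):
        with pytest.raises(GeometryError):
            fit_cn_axis(heptamer, 1)


class TestPdbIO:
    def test_round_trip_to_millangstrom(self, tmp_path, heptamer):
        path = tmp_path / "barrel.pdb"
        write_pdb(heptamer, path)
        back = read_pdb(path)
        assert len(back.chains) == 7
        assert all(len(c.residues) == 28 for c in back.chains)
        assert np.max(np.abs(back.coords() - heptamer.coords())) <= 1.5e-3

    def test_incomplete_residue_skipped_with_warning(self, tmp_path):
        model = _helix_model(9)
        # strip residue 5 down to CA only
        model.chains[0].residues[4].atoms = {
            "CA": model.chains[0].residues[4].atoms["CA"]}
        path = tmp_path / "partial.pdb"
        write_pdb(model, path)
        with pytest.warns(UserWarning, match="lacks"):
            back = read_pdb(path)
        assert len(back.chains[0].residues) == 8
        assert 5 not in [r.number for r in back.chains[0].residues]
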