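"""Fragment search, loop grafting and Cn-symmetric scaffold assembly."""

import numpy as np
import pytest

from barrelforge import fixtures
from barrelforge.connectors import (ClashError, FragmentHit, FragmentLibrary,
                                    assemble_parallel_scaffold, graft_connector,
                                    search_connectors, select_unit_handedness,
                                    stub_pair_from_helices)
from barrelforge.fixtures import HTHGeometry, make_hth_unit, make_loop_library
from barrelforge.geometry import (BACKBONE_ATOMS, BackboneModel, Chain,
                                  GeometryError, HelixSegment, Transform,
                                  backbone_rmsd, detect_helices,
                                  kabsch_superpose)


def brute_force_hits(query, library, rmsd_cutoff, max_loop_len=7, min_loop_len=0):
    """Independent exhaustive oracle: plain loops over all window pairs."""
    w = query.window
    target = query.coords()
    found = []
    for entry in library.entries:
        residues = entry.model.chains[0].residues
        for i in range(len(residues)):
            for j in range(len(residues)):
                if j - (i + w) < min_loop_len or j - (i + w) > max_loop_len:
                    continue
                if j + w > len(residues):
                    continue
                pts = []
                for k in list(range(i, i + w)) + list(range(j, j + w)):
                    for a in BACKBONE_ATOMS:
                        pts.append(residues[k].atoms[a])
                if len(pts) != 8 * w:
                    continue
                try:
                    _, rmsd = kabsch_superpose(np.asarray(pts), target)
                except GeometryError:
                    continue
                if rmsd <= rmsd_cutoff:
                    found.append((entry.source_id, residues[i].number,
                                  residues[j].number, rmsd))
    found.sort(key=lambda h: (h[3], h[0], h[1], h[2]))
    return found


class TestSearch:
    def test_self_query_retrieves_its_own_entry_first(self, loop_library):
        entry = loop_library.entries[2]
        query = stub_pair_from_helices(entry.model, *entry.model.helices)
        hits = search_connectors(query, loop_library, rmsd_cutoff=1.0)
        assert hits[0].source_id == entry.source_id
        assert hits[0].rmsd == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, loop_library):
        entry = loop_library.entries[0]
        query = stub_pair_from_helices(entry.model, *entry.model.helices)
        hits = search_connectors(query, loop_library, rmsd_cutoff=3.0)
        oracle = brute_force_hits(query, loop_library, rmsd_cutoff=3.0)
        assert len(hits) == len(oracle)
        for h, o in zip(hits, oracle):
            assert (h.source_id, h.range_a[0], h.range_b[0]) == o[:3]
            assert h.rmsd == pytest.approx(o[3], abs=1e-9)

    def test_zero_cutoff_on_perturbed_library_is_empty(self, loop_library):
        entry = loop_library.entries[1]
        query = stub_pair_from_helices(entry.model, *entry.model.helices)
        rng = np.random.default_rng(7)
        perturbed_entries = []
        for e in loop_library.entries:
            m = e.model.copy()
            for c in m.chains:
                for r in c.residues:
                    for a in r.atoms:
                        r.atoms[a] = r.atoms[a] + rng.normal(0, 0.2, 3)
            perturbed_entries.append(type(e)(e.source_id, m))
        perturbed = FragmentLibrary(perturbed_entries)
        assert search_connectors(query, perturbed, rmsd_cutoff=0.0) == []

    def test_hit_rmsd_invariant_to_rigid_query_motion(self, loop_library):
        entry = loop_library.entries[3]
        query = stub_pair_from_helices(entry.model, *entry.model.helices)
        hits0 = search_connectors(query, loop_library, rmsd_cutoff=3.0)
        t = Transform.rotation_about_axis(np.array([1.0, 2.0, 3.0]),
                                          np.array([0.0, 1.0, 0.0]), 0.8)
        for r in query.residues_a + query.residues_b:
            for a in r.atoms:
                r.atoms[a] = t.apply(r.atoms[a]) + np.array([10.0, -4.0, 2.0])
        hits1 = search_connectors(query, loop_library, rmsd_cutoff=3.0)
        assert [h.rmsd for h in hits1] == pytest.approx(
            [h.rmsd for h in hits0], abs=1e-6)

    def test_short_entries_warn_and_return_nothing(self, loop_library):
        entry = loop_library.entries[0]
        query = stub_pair_from_helices(entry.model, *entry.model.helices,
                                       window=5)
        stub_chain = Chain("A", [r.copy() for r in
                                 entry.model.chains[0].residues[:6]])
        tiny = FragmentLibrary([type(entry)("tiny", BackboneModel([stub_chain]))])
        with pytest.warns(UserWarning, match="shorter"):
            assert search_connectors(query, tiny, rmsd_cutoff=1.0) == []

    def test_long_loops_invisible_below_loop_cap(self):
        lib9 = make_loop_library(4, loop_lens=(9,), seed=3)
        entry = lib9.entries[0]
        query = stub_pair_from_helices(entry.model, *entry.model.helices)
        assert search_connectors(query, lib9, rmsd_cutoff=1.0,
                                 max_loop_len=7) == []
        hits = search_connectors(query, lib9, rmsd_cutoff=1.0, max_loop_len=9)
        assert hits and hits[0].rmsd == pytest.approx(0.0, abs=1e-6)


class TestGraft:
    def test_five_loops_fuse_hexamer_into_one_chain(self, grafted_hexamer_chain):
        model, results = grafted_hexamer_chain
        assert len(model.chains) == 1
        assert len(model.helices) == 6
        assert len(detect_helices(model)) == 6
        assert model.n_residues == 6 * 28 + 5 * 4
        assert model.validate_bonds() == []

    def test_junctions_are_peptide_bonds(self, grafted_hexamer_chain):
        _, results = grafted_hexamer_chain
        for res in results:
            assert res.unreconciled == []
            for _, d in res.junctions:
                assert 1.2 <= d <= 1.45

    def test_residue_bookkeeping(self, ap_hexamer):
        hi, hj = ap_hexamer.helices[0], ap_hexamer.helices[1]
        entry = fixtures.make_connectable_entry(ap_hexamer, hi, hj, loop_len=4,
                                                seed=11)
        query = stub_pair_from_helices(ap_hexamer, hi, hj)
        hits = search_connectors(query, FragmentLibrary([entry]), rmsd_cutoff=1.0)
        result = graft_connector(ap_hexamer, hits[0], hi, hj)
        merged = result.model.chains[0]
        assert len(merged.residues) == 28 + 4 + 28
        assert [r.number for r in merged.residues] == list(range(1, 61))
        assert result.renumbering[("A", 28)] == (merged.chain_id, 28)
        assert result.renumbering[("B", 1)] == (merged.chain_id, 33)

    def test_zero_length_loop_is_direct_fusion(self):
        res = fixtures.build_ideal_helix("A" * 24)
        first = Chain("A", [r.copy() for r in res[:12]])
        second = Chain("B", [r.copy() for r in res[12:]])
        for i, r in enumerate(second.residues):
            r.number = i + 1
        model = BackboneModel([first, second],
                              [HelixSegment("A", 1, 12), HelixSegment("B", 1, 12)])
        hit = FragmentHit("fusion", (1, 5), (6, 10), Transform.identity(), 0.0, [])
        result = graft_connector(model, hit, model.helices[0], model.helices[1])
        assert len(result.model.chains) == 1
        (junction,) = result.junctions
        assert junction[1] == pytest.approx(1.329, abs=0.01)

    def test_misaligned_hit_raises_clash_error(self, ap_hexamer):
        hi, hj = ap_hexamer.helices[0], ap_hexamer.helices[1]
        entry = fixtures.make_connectable_entry(ap_hexamer, hi, hj, loop_len=4,
                                                seed=11)
        query = stub_pair_from_helices(ap_hexamer, hi, hj)
        hits = search_connectors(query, FragmentLibrary([entry]), rmsd_cutoff=1.0)
        bad = FragmentHit(hits[0].source_id, hits[0].range_a, hits[0].range_b,
                          Transform.rotation_about_axis(np.zeros(3),
                                                        np.array([0, 0, 1.0]),
                                                        np.pi),
                          hits[0].rmsd, hits[0].loop_residues)
        with pytest.raises(ClashError):
            graft_connector(ap_hexamer, bad, hi, hj)


class TestScaffoldAssembly:
    def test_heptamer_gives_thirteen_helix_template(self, heptamer, hth_unit_7):
        result = assemble_parallel_scaffold(heptamer, hth_unit_7, 7)
        model = result.model
        assert len(model.chains) == 1
        assert len(model.helices) == 13
        assert len(detect_helices(model)) == 13
        assert result.unreconciled == []
        assert model.validate_bonds() == []

    @pytest.mark.parametrize("n,handedness,expected", [
        (5, "left", 9),
        (2, "right", 3),
    ])
    def test_helix_count_is_2n_minus_1(self, n, handedness, expected):
        unit = make_hth_unit(handedness, HTHGeometry(n=n))
        inner = fixtures.make_barrel(fixtures.CrickParams(n=n), 4)
        result = assemble_parallel_scaffold(inner, unit, n)
        assert len(result.model.helices) == expected

    def test_inner_helices_keep_cn_symmetry(self, heptamer, hth_unit_7):
        result = assemble_parallel_scaffold(heptamer, hth_unit_7, 7)
        model = result.model
        inner = [model.helices[2 * k] for k in range(7)]  # every other is inner
        first = BackboneModel([Chain("A", model.segment_residues(inner[0]))])
        for seg in inner[1:]:
            other = BackboneModel([Chain("A", model.segment_residues(seg))])
            assert backbone_rmsd(first, other) < 0.1

    def test_mismatched_unit_is_rejected(self, heptamer):
        unit5 = make_hth_unit("left", HTHGeometry(n=5))
        with pytest.raises(GeometryError):
            assemble_parallel_scaffold(heptamer, unit5, 7, tolerance=1.0)


class TestHandednessRule:
    @pytest.mark.parametrize("n,expected", [(5, "left"), (6, "right"),
                                            (7, "right"), (8, "right")])
    def test_handedness_by_barrel_order(self, n, expected):
        assert select_unit_handedness(n) == expected

    @pytest.mark.parametrize("n", [4, 9])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(ValueError):
            select_unit_handedness(n)
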