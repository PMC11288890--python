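"""Constraints, filters and convergence behaviour of the design loop."""

import numpy as np
import pytest

from barrelforge import design_loop, fixtures, geometry, registers
from barrelforge.design_loop import (Candidate, DesignConstraints,
                                     IdentityDesigner, IdentityPredictor,
                                     MockDesigner, SchedulePredictor,
                                     apply_filters, contact_energy, net_charge,
                                     run_design_loop,
                                     surface_hydrophobic_fraction)
from barrelforge.registers import (BackgroundSpec, HeptadSequence, SeedRule,
                                   ValidationError, build_seed_peptide)


@pytest.fixture(scope="module")
def scaffold_model(heptamer):
    chain = heptamer.chains[0]
    return geometry.BackboneModel(
        [chain], [h for h in heptamer.helices if h.chain_id == chain.chain_id])


class TestSurfaceHydrophobicity:
    def test_polar_surface_scores_zero(self, default_seq_4h):
        # default background: b/c Glu/Lys, f Gln/Lys except the Trp chromophore
        seq = build_seed_peptide(SeedRule("A", ("L",), ("I",), "A"),
                                 BackgroundSpec(["E", "E", "K", "K"],
                                                ["Q"], 4))
        assert surface_hydrophobic_fraction(seq) == 0.0

    def test_all_leucine_surface_scores_one(self):
        seq = HeptadSequence(["L"] * 28, offset="g")
        assert surface_hydrophobic_fraction(seq) == 1.0

    def test_single_trp_chromophore_counts_once(self, default_seq_4h):
        # 4 heptads -> 12 b/c/f sites, exactly one hydrophobic (the Trp at f)
        assert surface_hydrophobic_fraction(default_seq_4h) == pytest.approx(1 / 12)

    def test_unannotated_sequence_rejected(self):
        seq = HeptadSequence(["A"] * 7)
        seq.register = []
        with pytest.raises(ValidationError):
            surface_hydrophobic_fraction(seq)


class TestNetCharge:
    @pytest.mark.parametrize("s,q", [("EEKK", 0), ("EEEK", -2), ("KRH", 2),
                                     ("QQQQ", 0)])
    def test_direct_counts(self, s, q):
        assert net_charge(s) == q

    def test_bar_magnet_background_is_balanced(self):
        # Glu block and Lys block at b/c cancel by construction; neutral f
        seq = build_seed_peptide(SeedRule("A", ("L",), ("I",), "A"),
                                 BackgroundSpec(["E", "E", "K", "K"], ["Q"], 4))
        assert net_charge(seq) == 0


class TestContactEnergy:
    def test_packed_barrel_beats_isolated_helix(self, heptamer, scaffold_model):
        assert contact_energy(heptamer) < contact_energy(scaffold_model) <= 0.0


class TestApplyFilters:
    def test_empty_input_empty_output(self):
        passed, reports = apply_filters([])
        assert passed == [] and reports == []

    def test_duplicate_of_selected_is_rejected(self, default_seq_4h):
        cand = Candidate(default_seq_4h, energy=-10.0)
        passed, reports = apply_filters([cand], {"max_hydrophobic_fraction": 0.5},
                                        selected=[default_seq_4h])
        assert passed == []
        assert any("identity" in r for r in reports[0].reasons)

    def test_matches_brute_force_evaluation(self, default_seq_4h):
        rng = np.random.default_rng(5)
        thresholds = {"max_hydrophobic_fraction": 0.2, "max_abs_charge": 3,
                      "max_energy": -1.0, "max_identity": 85.0}
        cands = []
        for k in range(30):
            residues = list(default_seq_4h.residues)
            for _ in range(rng.integers(0, 8)):
                i = int(rng.integers(len(residues)))
                residues[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            seq = HeptadSequence(residues, offset="g", name=f"c{k}")
            cands.append(Candidate(seq, energy=float(rng.normal(-5, 4))))
        passed, _ = apply_filters(cands, thresholds)

        # independent greedy re-evaluation
        expected, kept = [], []
        for c in cands:
            ok = (surface_hydrophobic_fraction(c.sequence) <= 0.2
                  and abs(net_charge(c.sequence)) <= 3 and c.energy <= -1.0)
            if ok and all(registers.pairwise_identity(c.sequence, p) < 85.0
                          for p in kept):
                expected.append(c.sequence.name)
                kept.append(c.sequence)
        assert [c.sequence.name for c in passed] == expected


class TestConstraints:
    def test_overlapping_fixed_and_biased_rejected(self):
        with pytest.raises(ValidationError):
            DesignConstraints(fixed={1: "A"}, biased={1: {"K": 1.0}})

    def test_yaml_round_trip(self, tmp_path, default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        path = tmp_path / "constraints.yaml"
        cons.to_yaml(path)
        back = DesignConstraints.from_yaml(path)
        assert back.fixed == cons.fixed
        assert back.surface == cons.surface

    def test_scaffold_constraints_fix_interface_registers(self, default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        for lab in "gade":
            for i in default_seq_4h.positions(lab):
                assert cons.fixed[i] == default_seq_4h.residues[i]
        assert set(cons.surface) == {i for lab in "bcf"
                                     for i in default_seq_4h.positions(lab)}


class TestDesignLoop:
    def test_fixed_positions_survive_every_candidate(self, scaffold_model,
                                                     default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        designer = MockDesigner(default_seq_4h, seed=3, mutation_rate=0.5)
        for _ in range(3):
            for seq in designer.propose(scaffold_model, cons, 20):
                for i, aa in cons.fixed.items():
                    assert seq.residues[i] == aa

    def test_identity_mocks_converge_immediately(self, scaffold_model,
                                                 default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        result = run_design_loop(scaffold_model, cons, IdentityPredictor(),
                                 IdentityDesigner(default_seq_4h),
                                 max_rounds=10, batch_size=3)
        assert result.converged
        assert len(result.records) == 1
        assert result.records[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_decaying_schedule_converges_in_round_three(self, scaffold_model,
                                                        default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        result = run_design_loop(
            scaffold_model, cons,
            SchedulePredictor((0.8, 0.4, 0.1), seed=1),
            IdentityDesigner(default_seq_4h),
            max_rounds=10, batch_size=3, rmsd_tolerance=0.2)
        assert result.converged
        assert len(result.records) == 3

    def test_never_converging_run_reports_failure(self, scaffold_model,
                                                  default_seq_4h):
        cons = DesignConstraints.from_scaffold(default_seq_4h)
        result = run_design_loop(
            scaffold_model, cons,
            SchedulePredictor((2.0,), seed=1),
            IdentityDesigner(default_seq_4h),
            max_rounds=4, batch_size=3, rmsd_tolerance=0.2)
        assert not result.converged
        assert len(result.records) == 4
        assert result.final_sequence is None

    def test_run_is_bit_reproducible(self, scaffold_model, default_seq_4h,
                                     tmp_path):
        cons = DesignConstraints.from_scaffold(default_seq_4h)

        def run(path):
            return run_design_loop(
                scaffold_model, cons, SchedulePredictor((0.6, 0.3, 0.05), seed=9),
                MockDesigner(default_seq_4h, seed=9), max_rounds=5,
                batch_size=10, rmsd_tolerance=0.2, log_path=path)

        r1 = run(tmp_path / "a.jsonl")
        r2 = run(tmp_path / "b.jsonl")
        assert [rec.to_json() for rec in r1.records] == \
            [rec.to_json() for rec in r2.records]
        assert (tmp_path / "a.jsonl").read_text() == \
            (tmp_path / "b.jsonl").read_text()
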