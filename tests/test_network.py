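"""Structure and invariants of the polyQ/UPS/p38MAPK network."""

import numpy as np
import pytest

from polyqsim.engine import compile_model, simulate
from polyqsim.ensemble import run_ensemble
from polyqsim.network import (
    FEEDBACK_REACTION_ID,
    N_PROTEASOME,
    ScenarioConfig,
    build_halflife_model,
    build_polyq_model,
    build_ros_submodel,
    has_inclusion,
    oligomer_species,
    p38_death_hazard,
    proteasome_death_hazard,
)

PROTEASOME_POOLS = ["Proteasome", "AggP_Proteasome", "MisP_Proteasome", "SeqAggP_Proteasome"]


class TestModelStructure:
    def test_untreated_model_validates_and_contains_feedback(self):
        model = build_polyq_model(ScenarioConfig(treatment="untreated"))
        from polyqsim.core import validate_model

        assert validate_model(model) == []
        assert any(r.id == FEEDBACK_REACTION_ID for r in model.reactions)

    def test_feedback_off_removes_exactly_one_reaction(self):
        on = build_polyq_model(ScenarioConfig(feedback_on=True))
        off = build_polyq_model(ScenarioConfig(feedback_on=False))
        assert len(on.reactions) - len(off.reactions) == 1
        only_in_on = {r.id for r in on.reactions} - {r.id for r in off.reactions}
        assert only_in_on == {FEEDBACK_REACTION_ID}

    def test_seeding_consumes_six_monomers(self):
        """The inclusion seed is the pentamer-ladder top plus one monomer."""
        model = build_polyq_model(ScenarioConfig())
        seed = model.get_reaction("seedSeqAggP")
        assert dict(seed.reactants) == {"AggPolyQ5": 1, "PolyQ": 1}
        # AggPolyQ5 holds 6 monomers; the product tallies all six units
        assert dict(seed.products)["SeqAggP"] == 6

    def test_oligomer_ladder_is_reversible_below_seed_size(self):
        model = build_polyq_model(ScenarioConfig())
        ids = {r.id for r in model.reactions}
        for i in range(1, 6):
            assert f"disaggPolyQ{i}" in ids
        assert "disaggSeqAggP" not in ids  # inclusions never dissolve

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(treatment="aspirin")

    @pytest.mark.parametrize(
        "treatment, expect_event",
        [("PI", "PI_treatment"), ("BSO", "BSO_treatment")],
    )
    def test_treatments_apply_events_at_24h(self, treatment, expect_event):
        model = build_polyq_model(ScenarioConfig(treatment=treatment))
        ev = next(e for e in model.events if e.id == expect_event)
        assert ev.trigger == ("time", 24.0)

    def test_skf_zeroes_activation_from_time_zero(self):
        model = build_polyq_model(ScenarioConfig(treatment="SKF"))
        assert model.parameters["k_actp38"] == 0.0
        assert not any(e.id.startswith("SKF") for e in model.events)

    def test_death_events_zero_k_alive(self):
        model = build_polyq_model(ScenarioConfig())
        death_events = [e for e in model.events if e.id.endswith("_death")]
        assert len(death_events) == 2
        for ev in death_events:
            assert ev.assignments == (("k_alive", 0.0),)


class TestHazards:
    def test_p38_hazard_zero_without_active_kinase(self):
        assert p38_death_hazard(0, 1e-3) == 0.0

    def test_p38_hazard_linear(self):
        assert p38_death_hazard(40, 1e-3) == pytest.approx(2 * p38_death_hazard(20, 1e-3))

    def test_p38_hazard_positive_at_single_molecule(self):
        assert p38_death_hazard(1, 1e-3) > 0.0

    def test_proteasome_hazard_zero_at_zero_bound(self):
        assert proteasome_death_hazard(0, 500, 1.0) == 0.0

    def test_proteasome_hazard_monotone_in_bound(self):
        hazards = [proteasome_death_hazard(b, 500, 1.0) for b in range(0, 501, 25)]
        assert all(a <= b for a, b in zip(hazards, hazards[1:]))

    def test_proteasome_hazard_threshold_contrast(self):
        """Hazard at 50% bound is at least 10x the hazard at 10% bound."""
        h50 = proteasome_death_hazard(250, 500, 1.0)
        h10 = proteasome_death_hazard(50, 500, 1.0)
        assert h50 / h10 >= 10

    def test_proteasome_hazard_rejects_empty_total(self):
        with pytest.raises(ValueError):
            proteasome_death_hazard(0, 0, 1.0)


@pytest.fixture(scope="module")
def untreated_runs():
    scen = ScenarioConfig(treatment="untreated", n_runs=12, base_seed=97)
    return run_ensemble(scen).runs


class TestSimulatedInvariants:
    def test_proteasome_and_p38_conservation(self, untreated_runs):
        for traj in untreated_runs:
            prot = sum(traj.series(s) for s in PROTEASOME_POOLS)
            assert np.all(prot == N_PROTEASOME)
            assert np.all(traj.series("p38") + traj.series("p38_P") == 100)

    def test_seqaggp_never_decreases(self, untreated_runs):
        for traj in untreated_runs:
            assert np.all(np.diff(traj.series("SeqAggP")) >= 0)

    def test_inclusion_status_is_absorbing(self, untreated_runs):
        for traj in untreated_runs:
            flags = traj.series("SeqAggP") >= 1
            assert np.all(np.diff(flags.astype(int)) >= 0)

    def test_dead_cells_are_frozen(self, untreated_runs):
        for traj in untreated_runs:
            if traj.death_time is None:
                continue
            idx = np.searchsorted(traj.grid, traj.death_time)
            idx = min(idx, len(traj.grid) - 1)
            assert np.all(traj.samples[idx:] == traj.samples[idx])

    def test_skf_scenario_has_identically_zero_p38P(self):
        scen = ScenarioConfig(treatment="SKF", n_runs=6, base_seed=5)
        for traj in run_ensemble(scen).runs:
            assert np.all(traj.series("p38_P") == 0)
            assert traj.death_cause != "p38_death"


class TestHasInclusion:
    def test_counts_mapping(self):
        assert not has_inclusion({"SeqAggP": 0})
        assert has_inclusion({"SeqAggP": 1})

    def test_trajectory_at_time(self):
        scen = ScenarioConfig(treatment="PI", n_runs=4, base_seed=21)
        for traj in run_ensemble(scen).runs:
            flags = [has_inclusion(traj, t) for t in (24.0, 30.0, 36.0, 42.0, 48.0)]
            assert all(a <= b for a, b in zip(flags, flags[1:]))


class TestSubmodels:
    def test_ros_submodel_is_two_reactions(self):
        model = build_ros_submodel()
        assert {r.id for r in model.reactions} == {"genROS", "remROS"}
        assert model.species[0].initial_count == 10

    def test_halflife_model_disables_aggregation_and_binding(self):
        model = build_halflife_model("PolyQ", 24.0)
        assert model.parameters["k_nucPolyQ"] == 0.0
        assert model.parameters["k_inhprot"] == 0.0
        ev = next(e for e in model.events if e.id == "synthesis_shutoff")
        assert ev.trigger == ("time", 24.0)
        assert ev.assignments == (("k_synPolyQ", 0.0),)

    def test_halflife_model_rejects_other_species(self):
        with pytest.raises(ValueError):
            build_halflife_model("ROS", 24.0)
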