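"""Ensemble machinery: summary statistics, ablation, refit, half-life."""

import math

import numpy as np
import pandas as pd
import pytest

from polyqsim.ensemble import (
    EnsembleResult,
    ablate_feedback,
    fate_table,
    mean_mrfpu,
    measure_half_life,
    percent_dead,
    percent_with_inclusions,
    refit_no_feedback,
    replicate_seed,
    run_ensemble,
    summary_table,
)
from polyqsim.fixtures import FixtureSpec, make_fixture
from polyqsim.network import FEEDBACK_REACTION_ID, ScenarioConfig, build_polyq_model


@pytest.fixture(scope="module")
def small_untreated():
    return run_ensemble(ScenarioConfig(treatment="untreated", n_runs=20, base_seed=31))


class TestRunEnsemble:
    def test_reproducible_and_seeds_distinct(self):
        scen = ScenarioConfig(treatment="untreated", n_runs=3, base_seed=8)
        a, b = run_ensemble(scen), run_ensemble(scen)
        assert a.seeds == b.seeds and len(set(a.seeds)) == 3
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.samples, rb.samples)

    def test_replicate_seed_mixing_is_stable(self):
        assert replicate_seed(1, 0) == replicate_seed(1, 0)
        assert replicate_seed(1, 0) != replicate_seed(1, 1)
        assert 0 <= replicate_seed(2**20, 299) < 2**31


class TestPercentDead:
    def _fake(self, death_times, n):
        """Ensemble stub with prescribed fates (no simulation needed)."""
        from polyqsim.engine import Trajectory

        runs = []
        for i in range(n):
            dt = death_times[i] if i < len(death_times) else None
            runs.append(
                Trajectory(
                    grid=np.array([30.0]),
                    samples=np.zeros((1, 1), dtype=np.int64),
                    species=["SeqAggP"],
                    alive=dt is None,
                    death_cause="p38_death" if dt is not None else "none",
                    death_time=dt,
                )
            )
        scen = ScenarioConfig(n_runs=n)
        return EnsembleResult(scenario=scen, runs=runs, seeds=list(range(n)))

    def test_arithmetic(self):
        ens = self._fake([10.0] * 75, 300)
        point = percent_dead(ens, 30.0)
        assert point.values[0] == pytest.approx(25.0)

    def test_binomial_standard_error(self):
        ens = self._fake([10.0] * 75, 300)
        assert percent_dead(ens, 30.0).stderrs[0] == pytest.approx(
            math.sqrt(25 * 75 / 300)
        )

    def test_no_deaths_gives_zero_with_zero_se(self):
        ens = self._fake([], 100)
        point = percent_dead(ens, 30.0)
        assert point.values[0] == 0.0 and point.stderrs[0] == 0.0

    def test_invariant_to_run_order(self, small_untreated):
        shuffled = EnsembleResult(
            scenario=small_untreated.scenario,
            runs=list(reversed(small_untreated.runs)),
            seeds=list(reversed(small_untreated.seeds)),
        )
        assert (
            percent_dead(small_untreated, 30.0).values[0]
            == percent_dead(shuffled, 30.0).values[0]
        )


class TestInclusionAndReporterSeries:
    def test_inclusion_series_nondecreasing(self, small_untreated):
        series = percent_with_inclusions(small_untreated)
        assert np.all(np.diff(series.values) >= 0)

    def test_percentages_bounded_and_se_nonnegative(self, small_untreated):
        series = percent_with_inclusions(small_untreated)
        assert np.all((series.values >= 0) & (series.values <= 100))
        assert np.all(series.stderrs >= 0)

    def test_reporting_grid_matches_six_hour_cadence(self, small_untreated):
        series = percent_with_inclusions(small_untreated)
        assert list(series.timepoints) == [24.0, 30.0, 36.0, 42.0, 48.0]

    def test_mean_mrfpu_single_run_equals_its_value(self):
        ens = run_ensemble(ScenarioConfig(treatment="untreated", n_runs=1, base_seed=2))
        series = mean_mrfpu(ens, [24.0])
        assert series.values[0] == ens.runs[0].value_at("mRFPu", 24.0)
        assert series.n == 1


class TestAblateRefit:
    def test_ablation_removes_exactly_one_reaction(self):
        model = build_polyq_model(ScenarioConfig())
        ablated = ablate_feedback(model)
        assert len(model.reactions) - len(ablated.reactions) == 1
        assert all(r.id != FEEDBACK_REACTION_ID for r in ablated.reactions)

    def test_ablation_of_already_ablated_model_errors(self):
        model = build_polyq_model(ScenarioConfig(feedback_on=False))
        with pytest.raises(ValueError):
            ablate_feedback(model)

    def test_refit_identity_and_single_entry_scaling(self):
        params = {"k_aggPolyQ": 2.0, "k_p38death": 3.0}
        assert refit_no_feedback(params, {}) == params
        scaled = refit_no_feedback(params, {"k_aggPolyQ": 2.0})
        assert scaled["k_aggPolyQ"] == 4.0 and scaled["k_p38death"] == 3.0

    def test_refit_rejects_unknown_or_nonpositive(self):
        with pytest.raises(KeyError):
            refit_no_feedback({"a": 1.0}, {"b": 2.0})
        with pytest.raises(ValueError):
            refit_no_feedback({"a": 1.0}, {"a": 0.0})


class TestMeasureHalfLife:
    def test_first_order_decay_recovers_analytic_half_life(self):
        """k = ln2/20 -> measured halving time 20 h within 10%."""
        model, _ = make_fixture(
            FixtureSpec("pure_decay", {"k": math.log(2) / 20.0}, initial=2000)
        )
        scen = ScenarioConfig(treatment="untreated", n_runs=30, base_seed=3, horizon=70.0)
        ens = run_ensemble(scen, model=model)
        assert measure_half_life(ens, "X", 0.5) == pytest.approx(20.0, rel=0.10)

    def test_constant_pool_reports_censored(self):
        model, _ = make_fixture(FixtureSpec("pure_decay", {"k": 1e-9}, initial=100))
        scen = ScenarioConfig(treatment="untreated", n_runs=5, base_seed=3, horizon=10.0)
        ens = run_ensemble(scen, model=model)
        assert math.isinf(measure_half_life(ens, "X", 1.0))


class TestTables:
    def test_fate_table_schema_and_content(self, small_untreated):
        df = fate_table(small_untreated)
        assert list(df.columns) == [
            "run_id", "seed", "death_cause", "death_time_h", "inclusion_onset_time_h",
        ]
        assert len(df) == small_untreated.n
        dead = df[df.death_cause != "none"]
        assert dead.death_time_h.notna().all()

    def test_summary_table_stacks_three_metrics(self, small_untreated):
        df = summary_table(small_untreated)
        assert set(df.metric) == {"percent_dead", "percent_inclusions", "mean_mrfpu"}
        assert (df.n == small_untreated.n).all()
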