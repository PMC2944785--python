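"""SSA engine semantics: determinism, events, death freezing, exactness."""

import math

import numpy as np
import pytest

from polyqsim.core import EventDef, ModelDef, ReactionDef, SpeciesDef
from polyqsim.engine import apply_event, compile_model, simulate
from polyqsim.fixtures import FixtureSpec, make_fixture


def _model(species, reactions, parameters, events=()):
    return ModelDef(
        species=species, reactions=list(reactions),
        parameters=parameters, events=list(events),
    )


class TestSimulateBasics:
    def test_all_rates_zero_keeps_initial_counts(self, grid_48h):
        model = _model(
            [SpeciesDef("A", 7)],
            [ReactionDef("decay", (("A", 1),), (), "k")],
            {"k": 0.0},
        )
        traj = simulate(model, 48.0, grid_48h, seed=3)
        assert np.all(traj.series("A") == 7)
        assert traj.alive and traj.death_cause == "none"

    def test_single_forced_transition(self):
        model = _model(
            [SpeciesDef("A", 1)],
            [ReactionDef("decay", (("A", 1),), (), "k")],
            {"k": 100.0},
        )
        traj = simulate(model, 10.0, [5.0, 10.0], seed=1)
        assert traj.series("A")[-1] == 0

    def test_identical_seed_gives_bit_identical_trajectory(self, grid_48h):
        model, _ = make_fixture(FixtureSpec("immigration_death", {"lam": 20.0, "mu": 1.0}))
        a = simulate(model, 48.0, grid_48h, seed=42)
        b = simulate(model, 48.0, grid_48h, seed=42)
        assert np.array_equal(a.samples, b.samples)
        assert a.death_time == b.death_time

    def test_horizon_must_cover_grid(self):
        model, _ = make_fixture(FixtureSpec("pure_decay", {"k": 1.0}, initial=5))
        with pytest.raises(ValueError):
            simulate(model, 1.0, [0.5, 2.0], seed=1)

    def test_channel_selection_frequency_matches_propensity_ratio(self):
        """Two sources with rates 3:1 -> the faster fires 75% +- 3*SE of steps."""
        model = _model(
            [SpeciesDef("X", 0), SpeciesDef("Y", 0)],
            [
                ReactionDef("fast", (), (("X", 1),), "k_fast"),
                ReactionDef("slow", (), (("Y", 1),), "k_slow"),
            ],
            {"k_fast": 3.0, "k_slow": 1.0},
        )
        traj = simulate(model, 2500.0, [2500.0], seed=7)
        x, y = traj.samples[-1]
        n = x + y
        assert n > 9000
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(x / n - 0.75) < 3 * se


class TestEvents:
    def test_time_event_changes_parameter_at_trigger(self):
        """Source switched off at t=10: counts grow before, freeze after."""
        model = _model(
            [SpeciesDef("X", 0)],
            [ReactionDef("src", (), (("X", 1),), "k")],
            {"k": 50.0},
            [EventDef("off", ("time", 10.0), (("k", 0.0),))],
        )
        traj = simulate(model, 30.0, np.arange(1.0, 31.0), seed=5)
        x = traj.series("X")
        assert x[8] > 0
        assert np.all(x[10:] == x[10])
        assert 400 < x[10] < 600  # ~50/h for 10 h

    def test_event_fires_at_most_once(self):
        model = _model(
            [SpeciesDef("X", 0)],
            [ReactionDef("src", (), (("X", 1),), "k")],
            {"k": 10.0},
            [EventDef("bump", ("time", 5.0), (("X", 0),))],
        )
        traj = simulate(model, 20.0, np.arange(1.0, 21.0), seed=5)
        # X reset once at t=5 then accumulates undisturbed
        assert traj.series("X")[-1] > 100

    def test_no_event_model_unchanged_by_event_machinery(self, grid_48h):
        model, _ = make_fixture(FixtureSpec("immigration_death", {"lam": 5.0, "mu": 0.5}))
        bare = simulate(model, 48.0, grid_48h, seed=9)
        with_noop = model.copy()
        with_noop.events = [
            EventDef("never", ("time", 1e6), (("lam", 0.0),))
        ]
        assert np.array_equal(bare.samples, simulate(with_noop, 48.0, grid_48h, seed=9).samples)

    def test_species_threshold_event_zeroes_k_alive(self):
        """A death-flag crossing freezes the cell and records cause/time."""
        model = _model(
            [SpeciesDef("X", 0), SpeciesDef("p38_death_flag", 0, "flag")],
            [
                ReactionDef("src", (), (("X", 1),), "k"),
                ReactionDef("die", (), (("p38_death_flag", 1),), "k_die"),
            ],
            {"k": 100.0, "k_die": 0.5, "k_alive": 1.0},
            [EventDef("death", ("species_ge", "p38_death_flag", 1), (("k_alive", 0.0),))],
        )
        traj = simulate(model, 40.0, np.arange(0.5, 40.5, 0.5), seed=11)
        assert not traj.alive
        assert traj.death_cause == "p38_death"
        assert traj.death_time is not None
        # frozen after death: all samples past death_time equal the frozen state
        idx = np.searchsorted(traj.grid, traj.death_time)
        frozen = traj.samples[min(idx, len(traj.grid) - 1)]
        assert np.all(traj.samples[idx:] == frozen)

    def test_apply_event_rejects_undeclared_target(self):
        from polyqsim.engine import CellState

        state = CellState(counts={"A": 1})
        ev = EventDef("bad", ("time", 0.0), (("ghost", 1.0),))
        with pytest.raises(KeyError):
            apply_event(state, ev, {"k": 1.0})


class TestExactness:
    def test_immigration_death_matches_poisson_stationary_law(self):
        """Chi-square GoF of the t=50h ensemble against Poisson(lam/mu), alpha=0.01."""
        from scipy import stats

        lam, mu = 20.0, 1.0
        model, expected = make_fixture(
            FixtureSpec("immigration_death", {"lam": lam, "mu": mu}, initial=20)
        )
        compiled = compile_model(model)
        finals = np.array(
            [simulate(compiled, 50.0, [50.0], seed=1000 + i).samples[-1, 0] for i in range(200)]
        )
        m = expected["mean"]
        edges = [-0.5] + [m + k * math.sqrt(m) for k in (-1.5, -0.5, 0.5, 1.5)] + [np.inf]
        observed, _ = np.histogram(finals, bins=edges)
        probs = np.diff([stats.poisson.cdf(np.floor(e), m) if np.isfinite(e) else 1.0 for e in edges])
        probs[0] = stats.poisson.cdf(np.floor(edges[1]), m)
        chi2 = ((observed - 200 * probs) ** 2 / (200 * probs)).sum()
        crit = stats.chi2.ppf(0.99, df=len(observed) - 1)
        assert chi2 < crit

    def test_time_average_matches_stationary_mean(self):
        """Immigration-death time average over 50 h stays within 3 SE of lam/mu."""
        lam, mu = 20.0, 1.0
        model, _ = make_fixture(
            FixtureSpec("immigration_death", {"lam": lam, "mu": mu}, initial=20)
        )
        grid = np.arange(2, 101) * 0.5
        traj = simulate(model, 50.0, grid, seed=4)
        avg = traj.series("X").mean()
        # variance of the time average of an autocorrelated count process:
        # 2 * stationary variance * autocorrelation time / T
        se = math.sqrt(2 * (lam / mu) * (1 / mu) / 50.0)
        assert abs(avg - lam / mu) < 3 * se
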