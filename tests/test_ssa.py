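"""Gillespie simulator: distributional laws, estimators, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from conftest import birth_death_net, make_net, ring_net, source_net
from ctmc_oracle import stationary_means
from fspnsim.ssa import (
    MeasureDefinition,
    SimulationConfig,
    Trajectory,
    ensemble_summary,
    mser5_index,
    replications_for,
    simulate,
    simulate_ensemble,
    steady_state_mean,
    transient_mean,
    warmup_index,
)


class TestReproducibility:
    def test_same_seed_identical_trajectory(self):
        net = birth_death_net()
        cfg = SimulationConfig(end_time=50, seed=11)
        t1, t2 = simulate(net, cfg), simulate(net, cfg)
        assert np.array_equal(t1.states, t2.states)
        assert t1.n_events == t2.n_events

    def test_different_seeds_differ(self):
        net = birth_death_net()
        t1 = simulate(net, SimulationConfig(end_time=50, seed=1))
        t2 = simulate(net, SimulationConfig(end_time=50, seed=2))
        assert not np.array_equal(t1.states, t2.states)

    def test_ensemble_replications_are_isolated_streams(self):
        net = birth_death_net()
        cfg = SimulationConfig(end_time=20, seed=5, replications=3)
        trajs = simulate_ensemble(net, cfg)
        again = simulate_ensemble(net, cfg)
        for a, b in zip(trajs, again):
            assert np.array_equal(a.states, b.states)
        assert not np.array_equal(trajs[0].states, trajs[1].states)


class TestDistributionalLaws:
    def test_pure_birth_mean_is_poisson_rate_times_time(self):
        """For a source at rate 1, X(10) ~ Poisson(10)."""
        net = source_net(theta=1.0)
        cfg = SimulationConfig(end_time=10, seed=3, replications=400)
        est = transient_mean(
            simulate_ensemble(net, cfg), MeasureDefinition.place("X"), t=10
        )
        se = np.sqrt(10 / 400)
        assert est.mean == pytest.approx(10.0, abs=4 * se)
        assert est.ci_low < 10.0 < est.ci_high

    def test_event_counts_are_poisson(self):
        """Chi-square goodness of fit of firing counts against Poisson(lam*t)
        at the 1% level."""
        net = source_net(theta=2.0)
        lam_t = 2.0 * 5.0
        counts = [
            simulate(net, SimulationConfig(end_time=5, seed=s)).n_events
            for s in range(1000)
        ]
        counts = np.asarray(counts)
        edges = [0, 6, 8, 10, 12, 14, 100]
        observed = np.histogram(counts, bins=edges)[0]
        cdf = stats.poisson(lam_t).cdf
        probs = np.diff([0] + [cdf(e - 1) for e in edges[1:-1]] + [1.0])
        expected = probs * len(counts)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_interevent_times_are_exponential(self):
        """KS test of waiting times in a constant-hazard net at the 1% level."""
        net = source_net(theta=2.0)
        traj = simulate(
            net, SimulationConfig(end_time=1000, seed=4), record_events=True
        )
        waits = np.diff(np.concatenate([[0.0], traj.event_times]))
        _, p = stats.kstest(waits, "expon", args=(0, 1 / 2.0))
        assert p > 0.01

    def test_mm_infinity_long_run_mean(self):
        """Birth-death with lam=5, mu=1 has stationary mean lam/mu = 5."""
        net = birth_death_net(lam=5.0, mu=1.0)
        traj = simulate(net, SimulationConfig(end_time=3000, seed=8))
        assert steady_state_mean(traj, "X") == pytest.approx(5.0, abs=0.4)

    def test_ctmc_oracle_equivalence(self):
        """SSA long-run means match the stationary solve of the explicit
        CTMC on small bounded nets, within 3 Monte-Carlo standard errors."""
        nets = [
            ring_net(theta_ab=2.0, theta_ba=3.0, tokens=5),
            # dimerization ring exercises binomial combination hazards
            make_net(
                ["X", "Y"],
                [("dim", 0.5), ("dis", 1.0)],
                [("X", "dim", 2), ("dim", "Y"), ("Y", "dis"), ("dis", "X", 2)],
                {"X": 6, "Y": 0},
            ),
        ]
        for net in nets:
            exact = stationary_means(net, max_states=100)
            for place in net.place_ids:
                reps = [
                    steady_state_mean(
                        simulate(net, SimulationConfig(end_time=400, seed=s)),
                        place,
                        warmup=0.1,
                    )
                    for s in range(16)
                ]
                mc_mean = np.mean(reps)
                se = np.std(reps, ddof=1) / np.sqrt(len(reps))
                assert abs(mc_mean - exact[place]) < 3 * se + 1e-6, (
                    f"{net.name}:{place} SSA {mc_mean:.3f} vs CTMC {exact[place]:.3f}"
                )

    def test_dead_marking_freezes_state(self):
        net = make_net(["X"], [("decay", 1.0)], [("X", "decay")], {"X": 3})
        traj = simulate(net, SimulationConfig(end_time=100, seed=9))
        x = traj.series("X")
        assert x[0] == 3 and x[-1] == 0
        assert np.all(np.diff(x) <= 0)
        first_zero = np.argmax(x == 0)
        assert np.all(x[first_zero:] == 0)

    def test_no_enabled_transition_warns_constant(self):
        net = make_net(["X"], [("decay", 1.0)], [("X", "decay")], {"X": 0})
        with pytest.warns(UserWarning, match="no transition is enabled"):
            traj = simulate(net, SimulationConfig(end_time=10, seed=1))
        assert np.all(traj.series("X") == 0)


class TestTransientEstimator:
    def test_single_replication_has_undefined_ci(self):
        net = birth_death_net()
        est = transient_mean(
            [simulate(net, SimulationConfig(end_time=10, seed=1))],
            MeasureDefinition.place("X"),
            t=10,
        )
        assert est.n == 1
        assert np.isnan(est.variance) and np.isnan(est.ci_low)

    def test_identical_replications_have_zero_variance(self):
        net = birth_death_net()
        traj = simulate(net, SimulationConfig(end_time=10, seed=1))
        est = transient_mean([traj, traj, traj], MeasureDefinition.place("X"), t=10)
        assert est.variance == 0.0
        assert est.mean == traj.series("X")[-1]

    def test_time_beyond_horizon_rejected(self):
        net = birth_death_net()
        trajs = [simulate(net, SimulationConfig(end_time=10, seed=s)) for s in (1, 2)]
        with pytest.raises(ValueError, match="beyond"):
            transient_mean(trajs, MeasureDefinition.place("X"), t=20)

    def test_mismatched_grids_rejected(self):
        net = birth_death_net()
        a = simulate(net, SimulationConfig(end_time=10, seed=1))
        b = simulate(net, SimulationConfig(end_time=20, seed=1))
        with pytest.raises(ValueError, match="grid"):
            ensemble_summary([a, b], MeasureDefinition.place("X"))

    def test_weighted_sum_measure(self, yeast):
        traj = simulate(yeast, SimulationConfig(end_time=20, seed=2))
        m = MeasureDefinition.parse("G+Gbg:steady")
        assert np.all(traj.series(m) == 320)


class TestSteadyStateEstimator:
    def _traj(self, values):
        arr = np.asarray(values, dtype=np.int64).reshape(-1, 1)
        return Trajectory(
            times=np.arange(len(values), dtype=float),
            states=arr,
            place_ids=["X"],
        )

    def test_truncation_arithmetic(self):
        traj = self._traj([0, 0, 0, 10, 10, 10])
        assert steady_state_mean(traj, "X", warmup=3) == 10.0
        assert steady_state_mean(traj, "X", warmup=0) == 5.0

    def test_constant_series_any_warmup(self):
        traj = self._traj([7] * 20)
        for warmup in (0, 5, 0.3, "mser5"):
            assert steady_state_mean(traj, "X", warmup=warmup) == 7.0

    def test_warmup_exhausting_series_rejected(self):
        traj = self._traj([1, 2, 3])
        with pytest.raises(ValueError, match="no observations"):
            steady_state_mean(traj, "X", warmup=3)

    def test_mser5_detects_initial_transient(self):
        rng = np.random.default_rng(0)
        y = np.concatenate(
            [np.full(50, 100.0), rng.normal(0.0, 1.0, 450)]
        )
        idx = mser5_index(y)
        assert 45 <= idx <= 60

    def test_mser5_short_series_returns_zero(self):
        assert mser5_index(np.arange(7)) == 0

    def test_fraction_warmup(self):
        assert warmup_index(np.arange(100), 0.1) == 10
        with pytest.raises(ValueError, match="fraction"):
            warmup_index(np.arange(10), 1.5)


class TestReplicationsFor:
    @pytest.mark.parametrize(
        "confidence, accuracy, expected",
        [(0.95, 0.1, 185), (0.95, 0.01, 18445)],
    )
    def test_bound_values(self, confidence, accuracy, expected):
        assert replications_for(confidence, accuracy) == expected

    def test_quadratic_scaling_in_accuracy(self):
        # confidence chosen so the bound is exactly 1/accuracy^2
        conf = 1 - 2 / np.e**2
        assert replications_for(conf, 0.1) == 100
        assert replications_for(conf, 0.05) == 400

    def test_monotone(self):
        assert replications_for(0.99, 0.1) >= replications_for(0.95, 0.1)
        assert replications_for(0.95, 0.05) >= replications_for(0.95, 0.1)

    @pytest.mark.parametrize("confidence, accuracy", [(0.0, 0.1), (1.0, 0.1), (0.95, 0.0)])
    def test_invalid_arguments(self, confidence, accuracy):
        with pytest.raises(ValueError):
            replications_for(confidence, accuracy)


class TestMeasureParsing:
    @pytest.mark.parametrize(
        "text, weights, stat, time",
        [
            ("G:steady", {"G": 1.0}, "steady_state_mean", None),
            ("G:mean@100", {"G": 1.0}, "mean_at_time", 100.0),
            ("G+Gbg:steady", {"G": 1.0, "Gbg": 1.0}, "steady_state_mean", None),
        ],
    )
    def test_parse(self, text, weights, stat, time):
        m = MeasureDefinition.parse(text)
        assert dict(m.weights) == weights
        assert m.statistic == stat and m.time == time

    def test_parse_rejects_unknown_statistic(self):
        with pytest.raises(ValueError):
            MeasureDefinition.parse("G:median")
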