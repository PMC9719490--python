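"""Closed-loop homing: initialisation, estimators, convergence, batches."""

import numpy as np
import pytest

from batnav import (
    Dataset,
    Estimator,
    SimConfig,
    bearing_to_target,
    init_state,
    make_model_estimator,
    make_noisy_oracle,
    make_phototaxis_estimator,
    run_batch,
    sd_for_mean_abs_error,
    simulate,
)
from batnav.angles import wrap_signed
from batnav.errors import SimulationError

MICRO_SIM = SimConfig(start_zone_m=(0.0, 500.0), max_steps=40)


class TestInitState:
    def test_degenerate_jitter(self, tiny_world, tiny_trajectory):
        cfg = SimConfig(start_zone_m=(0.0, 500.0), heading_jitter_deg=(0.0, 0.0))
        pos, heading = init_state(tiny_trajectory, tiny_world, cfg, seed=3)
        assert heading == pytest.approx(bearing_to_target(pos, tiny_world.goal) % 360.0)

    def test_start_zone_coverage(self, tiny_world, tiny_trajectory):
        cfg = SimConfig(start_zone_m=(0.0, 500.0), heading_jitter_deg=(-30.0, 30.0))
        for seed in range(200):
            pos, heading = init_state(tiny_trajectory, tiny_world, cfg, seed=seed)
            assert tiny_trajectory.min_distance_to(pos) < 1e-6
            # on the near-straight tiny route, arc position ~ distance from origin
            assert np.hypot(*(pos - tiny_trajectory.waypoints[0])) <= 505.0
            rel = wrap_signed(heading - bearing_to_target(pos, tiny_world.goal))
            assert -30.0 <= rel <= 30.0

    def test_deterministic(self, tiny_world, tiny_trajectory):
        a = init_state(tiny_trajectory, tiny_world, MICRO_SIM, seed=9)
        b = init_state(tiny_trajectory, tiny_world, MICRO_SIM, seed=9)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]


class TestNoisyOracle:
    def test_exact_oracle(self, tiny_world):
        est = make_noisy_oracle(tiny_world, 0.0, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            pos = rng.uniform(-1_000, 1_000, 2)
            heading = rng.uniform(0, 360)
            truth = wrap_signed(heading - bearing_to_target(pos, tiny_world.goal))
            assert est.estimate(pos, heading) == pytest.approx(truth)

    def test_halfnormal_calibration(self, tiny_world):
        """sd = m*sqrt(pi/2) gives mean |noise| = m: 27.8 deg -> 22.2 deg."""
        sd = sd_for_mean_abs_error(22.2)
        assert sd == pytest.approx(27.8, abs=0.05)
        est = make_noisy_oracle(tiny_world, sd, seed=12)
        pos, heading = (0.0, 100.0), 0.0
        truth = wrap_signed(heading - bearing_to_target(pos, tiny_world.goal))
        noises = [wrap_signed(est.estimate(pos, heading) - truth) for _ in range(10_000)]
        assert np.mean(np.abs(noises)) == pytest.approx(22.2, abs=0.5)

    def test_deterministic_sequences(self, tiny_world):
        a = make_noisy_oracle(tiny_world, 20.0, seed=4)
        b = make_noisy_oracle(tiny_world, 20.0, seed=4)
        seq_a = [a.estimate((0.0, 0.0), 10.0) for _ in range(5)]
        seq_b = [b.estimate((0.0, 0.0), 10.0) for _ in range(5)]
        assert seq_a == seq_b


class TestSimulate:
    def test_exact_oracle_geometric_convergence(self, tiny_world, tiny_trajectory):
        est = make_noisy_oracle(tiny_world, 0.0, seed=0)
        cfg = MICRO_SIM
        result = simulate(tiny_world, tiny_trajectory, est, cfg, seed=2)
        assert result.success
        d0 = result.distances[0]
        bound = int(np.ceil(d0 / cfg.step_m)) + cfg.orbit_steps
        assert result.steps_used <= bound
        # strictly decreasing approach until within one step of the goal
        d = result.distances
        while_approaching = d[:-1] > cfg.step_m
        assert np.all(np.diff(d)[while_approaching[: len(d) - 1]] < 0)

    def test_step_length_conservation(self, tiny_world, tiny_trajectory):
        est = make_noisy_oracle(tiny_world, 30.0, seed=5)
        result = simulate(tiny_world, tiny_trajectory, est, MICRO_SIM, seed=3)
        steps = np.hypot(*np.diff(result.positions, axis=0).T)
        assert np.allclose(steps, MICRO_SIM.step_m, atol=1e-6)

    def test_degenerate_start_near_goal(self, tiny_world):
        from batnav.trajectory import Trajectory

        goal = np.asarray(tiny_world.goal)
        near = Trajectory(np.stack([goal - (100.0, 0.0), goal - (0.1, 0.0)], axis=0))
        cfg = SimConfig(start_zone_m=(0.0, 50.0), max_steps=10)
        est = make_noisy_oracle(tiny_world, 0.0, seed=0)  # steers to stay near the goal
        result = simulate(tiny_world, near, est, cfg, seed=0)
        assert result.success
        assert result.steps_used <= cfg.orbit_steps

    def test_antipodal_estimator_never_converges(self, tiny_world, tiny_trajectory):
        goal = np.asarray(tiny_world.goal)

        def wrong(pos, heading):
            return wrap_signed(heading - bearing_to_target(pos, goal) + 180.0)

        est = Estimator(fn=wrong, kind="noisy_oracle")
        result = simulate(tiny_world, tiny_trajectory, est, MICRO_SIM, seed=1)
        assert not result.success
        assert result.steps_used == MICRO_SIM.max_steps

    def test_nonfinite_estimate_raises(self, tiny_world, tiny_trajectory):
        est = Estimator(fn=lambda p, h: float("nan"), kind="noisy_oracle")
        with pytest.raises(SimulationError):
            simulate(tiny_world, tiny_trajectory, est, MICRO_SIM, seed=0)


class TestRunBatch:
    def test_exact_and_antipodal_rates(self, tiny_world, tiny_trajectory):
        goal = np.asarray(tiny_world.goal)
        exact = make_noisy_oracle(tiny_world, 0.0, seed=0)
        wrong = Estimator(
            fn=lambda p, h: wrap_signed(h - bearing_to_target(p, goal) + 180.0), kind="noisy_oracle"
        )
        batch = run_batch(tiny_world, tiny_trajectory, [exact, wrong], 5, MICRO_SIM, seed=0)
        assert batch.successes == [5, 0]
        assert batch.pooled_rate == 0.5

    def test_success_monotone_in_noise(self, tiny_world, tiny_trajectory):
        """More estimator noise never helps: rates ordered for sd 0/28/90."""
        rates = []
        for sd in (0.0, 28.0, 90.0):
            est = make_noisy_oracle(tiny_world, sd, seed=7)
            batch = run_batch(tiny_world, tiny_trajectory, [est], 50, MICRO_SIM, seed=11)
            rates.append(batch.rates[0])
        assert rates[0] >= rates[1] >= rates[2]


class TestModelEstimator:
    def _lookup_dataset(self, tiny_world):
        positions = np.array([[0.0, 0.0], [0.0, 500.0], [200.0, 200.0]])
        gazes = np.array([10.0, 200.0, 355.0])
        labels = wrap_signed(gazes - bearing_to_target(positions, np.asarray(tiny_world.goal)))
        n = len(gazes)
        return Dataset(
            images=np.zeros((n, 2, 2, 2), dtype=np.float32),
            positions=positions,
            gazes=gazes,
            labels=np.asarray(labels),
            arc_m=np.zeros(n),
            split=np.full(n, "train", dtype="U8"),
        )

    def test_nearest_view_exact_query(self, tiny_world):
        ds = self._lookup_dataset(tiny_world)
        est = make_model_estimator(None, ds, lookup_mode="nearest_view")
        for i in range(len(ds)):
            got = est.estimate(ds.positions[i], float(ds.gazes[i]))
            assert got == pytest.approx(float(ds.labels[i]))

    def test_nearest_view_gaze_correction(self, tiny_world):
        ds = self._lookup_dataset(tiny_world)
        est = make_model_estimator(None, ds, lookup_mode="nearest_view")
        pos = ds.positions[1]
        heading = float((ds.gazes[1] + 25.0) % 360.0)
        truth = wrap_signed(heading - bearing_to_target(pos, np.asarray(tiny_world.goal)))
        assert est.estimate(pos, heading) == pytest.approx(float(truth))

    def test_nearest_view_tie_breaks_to_lowest_index(self, tiny_world):
        positions = np.array([[0.0, 100.0], [0.0, -100.0]])  # equidistant from origin
        gazes = np.array([0.0, 0.0])
        labels = np.array([5.0, -40.0])
        ds = Dataset(
            images=np.zeros((2, 2, 2, 2), dtype=np.float32),
            positions=positions,
            gazes=gazes,
            labels=labels,
            arc_m=np.zeros(2),
            split=np.full(2, "train", dtype="U8"),
        )
        est = make_model_estimator(None, ds, lookup_mode="nearest_view", correct_gaze_mismatch=False)
        assert est.estimate((0.0, 0.0), 0.0) == pytest.approx(5.0)

    def test_render_exact_passthrough(self, tiny_world):
        class Stub:
            def predict(self, images):
                return np.full(len(images), 42.0)

        est = make_model_estimator(Stub(), tiny_world, lookup_mode="render_exact")
        assert est.estimate((0.0, 0.0), 90.0) == pytest.approx(42.0)


def test_phototaxis_baseline_fails_with_offgoal_city(tiny_world, tiny_trajectory):
    """Brightest-direction steering never captures the (unlit) goal when the
    dominant city sits off the route: 0/50 runs succeed."""
    est = make_phototaxis_estimator(tiny_world)
    batch = run_batch(tiny_world, tiny_trajectory, [est], 50, MICRO_SIM, seed=2)
    assert batch.successes == [0]
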