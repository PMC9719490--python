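"""Synthetic landscape, trajectory, renderer and light-profile behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from batnav import (
    DriftConfig,
    RenderConfig,
    TrajectoryConfig,
    WorldConfig,
    angular_light_profile,
    build_world,
    make_trajectory,
    perturb_world,
    render_view,
)
from batnav.errors import ConfigurationError, GenerationError
from batnav.render import source_pixel_column
from batnav.world import LightSource, World
from conftest import make_single_source_world


class TestBuildWorld:
    def test_deterministic_and_seed_sensitive(self):
        a = build_world(WorldConfig(), seed=1)
        b = build_world(WorldConfig(), seed=1)
        c = build_world(WorldConfig(), seed=2)
        assert a == b
        assert a.light_sources != c.light_sources

    def test_default_origin_goal_distance(self):
        w = build_world(seed=5)
        assert w.goal_distance == pytest.approx(17_200.0, abs=1.0)

    @pytest.mark.parametrize(
        "cfg, named",
        [
            (WorldConfig(goal_distance_m=-5.0), "goal_distance_m"),
            (WorldConfig(n_light_sources=0), "n_light_sources"),
            (WorldConfig(radiance_median=0.0), "radiance_median"),
        ],
    )
    def test_invalid_config_names_field(self, cfg, named):
        with pytest.raises(ConfigurationError, match=named):
            build_world(cfg, seed=0)

    def test_dominant_city_invariant(self):
        w = build_world(seed=3)
        dom = w.dominant_source
        others = [s.peak_radiance for s in w.light_sources if s is not dom]
        assert dom.peak_radiance > 10.0 * np.median(others)


class TestTrajectory:
    def test_straight_route_length(self):
        w = build_world(seed=1)
        t = make_trajectory(w, TrajectoryConfig(lateral_amplitude_m=0.0), seed=0)
        assert t.length == pytest.approx(17_200.0, rel=1e-3)

    def test_arc_at_least_chord_and_curvature(self):
        w = build_world(seed=1)
        t = make_trajectory(w, seed=4)
        assert t.length >= w.goal_distance
        assert np.all(np.diff(t.cum_length) > 0)
        assert np.max(np.diff(t.cum_length)) <= 50.0
        headings = t.headings_deg()
        turns = np.abs((np.diff(headings) + 180) % 360 - 180)
        assert turns.max() <= 15.0

    def test_endpoints(self):
        w = build_world(seed=1)
        t = make_trajectory(w, seed=4)
        assert np.allclose(t.waypoints[0], w.origin)
        assert np.hypot(*(t.waypoints[-1] - np.asarray(w.goal))) <= 50.0

    def test_deterministic(self):
        w = build_world(seed=1)
        assert np.array_equal(make_trajectory(w, seed=9).waypoints, make_trajectory(w, seed=9).waypoints)

    def test_infeasible_curvature_raises(self):
        w = build_world(seed=1)
        with pytest.raises(GenerationError):
            make_trajectory(w, TrajectoryConfig(lateral_amplitude_m=4_000.0, lateral_periods=30.0), seed=0)


class TestRenderer:
    def test_gaze_wrap_identity(self):
        w = make_single_source_world()
        a = render_view(w, (100.0, 100.0), 42.0)
        b = render_view(w, (100.0, 100.0), 402.0)
        assert np.array_equal(a, b)

    def test_deterministic(self):
        w = make_single_source_world()
        a = render_view(w, (30.0, -40.0), 123.4)
        b = render_view(w, (30.0, -40.0), 123.4)
        assert a.tobytes() == b.tobytes()

    def test_projection_oracle_random_draws(self):
        """Brightest middle-band column matches the analytic perspective
        projection of the source azimuth within 2 columns (100 draws)."""
        rng = np.random.default_rng(42)
        cfg = RenderConfig(resolution=64)
        w = make_single_source_world(radiance=8.0)
        from batnav import bearing_to_target, wrap_signed

        checked = 0
        while checked < 100:
            pos = rng.uniform(-3_000, 3_000, size=2)
            src_az = bearing_to_target(pos, w.light_sources[0].position)
            gaze = (src_az + rng.uniform(-30.0, 30.0)) % 360.0  # keep the source well inside the FOV
            rel = wrap_signed(src_az - gaze)
            img = render_view(w, pos, gaze, cfg)
            third = 64 // 3
            col = int(np.argmax(img[third : 2 * third].sum(axis=(0, 2))))
            expected = source_pixel_column(rel, 64, cfg.fov_deg)
            assert abs(col - expected) <= 2.0
            checked += 1

    def test_source_aimed_at_center(self):
        w = make_single_source_world(radiance=8.0)
        from batnav import bearing_to_target

        pos = (500.0, -1_000.0)
        gaze = bearing_to_target(pos, w.light_sources[0].position)
        img = render_view(w, pos, gaze, RenderConfig(resolution=64))
        third = 64 // 3
        col = int(np.argmax(img[third : 2 * third].sum(axis=(0, 2))))
        assert abs(col - 64 // 2) <= 2

    def test_dark_world_middle_band(self):
        w = make_single_source_world(radiance=0.0)
        img = render_view(w, (0.0, 100.0), 10.0)
        third = 64 // 3
        mid = img[third : 2 * third]
        assert float(mid.max() - mid.min()) < 0.01


class TestPerturbWorld:
    def test_zero_drift_identity(self):
        w = build_world(seed=2)
        assert perturb_world(w, DriftConfig(fraction=0.0), seed=5) == w

    def test_deterministic(self):
        w = build_world(seed=2)
        assert perturb_world(w, seed=5) == perturb_world(w, seed=5)

    def test_modified_count_binomial(self):
        w = build_world(WorldConfig(n_light_sources=49), seed=2)  # 50 sources with the city
        counts = []
        for seed in range(20):
            p = perturb_world(w, DriftConfig(fraction=0.2), seed=seed)
            counts.append(sum(a != b for a, b in zip(w.light_sources, p.light_sources)))
        expected = 0.2 * 49  # the dominant city is never modified
        assert abs(np.mean(counts) - expected) < 2.0

    def test_dominant_city_retained(self):
        w = build_world(seed=2)
        p = perturb_world(w, DriftConfig(fraction=1.0), seed=1)
        assert w.dominant_source in p.light_sources


class TestAngularLightProfile:
    def _world_with(self, sources):
        return World(
            light_sources=tuple(sources),
            ground_texture_seed=0,
            sky_gradient_params=(0.06, 0.14),
            origin=(0.0, 0.0),
            goal=(0.0, 2_000.0),
            seed=0,
            config=WorldConfig(goal_distance_m=2_000.0, n_light_sources=len(sources)),
        )

    def test_single_source_north(self):
        w = self._world_with([LightSource((0.0, 3_000.0), 1.0, 200.0, (0.5, 0.4))])
        prof = angular_light_profile(w, (0.0, 0.0), radius_m=5_000.0, n_bins=12)
        north_bin = np.argmin(np.abs(prof.bin_centers_deg))
        assert prof.fraction_of_total[north_bin] == pytest.approx(1.0)

    def test_opposite_equal_sources(self):
        w = self._world_with(
            [
                LightSource((0.0, 3_000.0), 1.0, 200.0, (0.5, 0.4)),
                LightSource((0.0, -3_000.0), 1.0, 200.0, (0.5, 0.4)),
            ]
        )
        prof = angular_light_profile(w, (0.0, 0.0), radius_m=5_000.0, n_bins=12)
        assert sorted(prof.fraction_of_total, reverse=True)[:2] == [pytest.approx(0.5)] * 2

    def test_default_world_normalised(self):
        w = build_world(seed=1)
        prof = angular_light_profile(w, w.origin, radius_m=15_000.0, n_bins=36)
        assert prof.fraction_of_total.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(prof.fraction_of_total >= 0)

    def test_rotation_equivariance(self):
        sources = [
            LightSource((2_000.0, 1_000.0), 2.0, 300.0, (0.5, 0.4)),
            LightSource((-500.0, 2_500.0), 1.0, 200.0, (0.5, 0.4)),
        ]
        w = self._world_with(sources)
        delta = 30.0  # one bin
        rad = np.radians(delta)
        rot = np.array([[np.cos(rad), np.sin(rad)], [-np.sin(rad), np.cos(rad)]])
        # p' = R p shifts every azimuth clockwise by +delta
        rotated = [replace(s, position=tuple(rot @ np.asarray(s.position))) for s in sources]
        w2 = self._world_with(rotated)
        a = angular_light_profile(w, (0.0, 0.0), 5_000.0, n_bins=12)
        b = angular_light_profile(w2, (0.0, 0.0), 5_000.0, n_bins=12)
        assert np.allclose(np.roll(a.fraction_of_total, 1), b.fraction_of_total, atol=1e-9)

    def test_empty_radius_raises(self):
        w = self._world_with([LightSource((0.0, 9_000.0), 1.0, 200.0, (0.5, 0.4))])
        with pytest.raises(ConfigurationError, match="no light sources"):
            angular_light_profile(w, (0.0, 0.0), radius_m=1_000.0, n_bins=12)
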