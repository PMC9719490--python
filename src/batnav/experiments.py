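"""Canonical desk-scale experiment drivers.

These functions define the study conditions used by the analysis scripts,
the acceptance recomputation and the heavier tests: the default 17.2 km
synthetic world, the route acquisition at 64x64, the compact network and
its training schedule, the excluded-segment generalisation protocol, and
the noise-calibrated closed-loop simulation batch.  Keeping them here means
every consumer measures the same quantities on the same conditions.
"""

from __future__ import annotations

import numpy as np

from .acquisition import Dataset, ProtocolConfig, _render_degraded, sample_route_views, split_exclude_segment
from .angles import bearing_to_target, relative_gaze
from .navnet import ArchConfig, ErrorSummary, Hyperparams, TrainedModel, build_model, sector_error, train_model
from .pipeline import child_seed
from .simulator import SimConfig, make_noisy_oracle, run_batch, sd_for_mean_abs_error
from .trajectory import Trajectory, TrajectoryConfig, make_trajectory
from .world import World, WorldConfig, build_world

__all__ = [
    "default_world",
    "default_trajectory",
    "desk_protocol",
    "desk_arch",
    "desk_hyper",
    "make_route_dataset",
    "fresh_test_views",
    "default_exclusion_ranges",
    "experiment_full_route",
    "experiment_generalization",
    "experiment_sim_success",
]

#: mean |error| figures of the two reference networks (full data; excluded
#: segment) used to calibrate the noisy-oracle estimators of the simulation.
REFERENCE_MEAN_ERRORS = (22.2, 25.4)

DESK_EPOCHS = 16


def default_world(seed: int = 0) -> World:
    return build_world(WorldConfig(), seed)


def default_trajectory(world: World, seed: int = 0) -> Trajectory:
    return make_trajectory(world, TrajectoryConfig(), seed)


def desk_protocol(resolution: int = 64) -> ProtocolConfig:
    return ProtocolConfig(resolution=resolution)


def desk_arch(resolution: int = 64) -> ArchConfig:
    return ArchConfig(input_hw=(resolution, resolution))


def desk_hyper(seed: int = 0, epochs: int = DESK_EPOCHS) -> Hyperparams:
    decay = (epochs * 3 // 8, epochs * 5 // 8, epochs * 13 // 16)
    return Hyperparams(epochs=epochs, seed=seed, clip_norm=5.0, lr_decay_epochs=decay)


def make_route_dataset(world: World, trajectory: Trajectory, seed: int = 0,
                       protocol: ProtocolConfig | None = None) -> Dataset:
    return sample_route_views(world, trajectory, protocol or desk_protocol(), seed)


def fresh_test_views(
    world: World,
    trajectory: Trajectory,
    n: int = 600,
    seed: int = 0,
    gaze_halfwidth_deg: float = 60.0,
    lateral_jitter_m: float = 50.0,
    arc_range_m: tuple[float, float] | None = None,
    protocol: ProtocolConfig | None = None,
) -> Dataset:
    """Freshly rendered test views at jittered positions and gazes.

    Positions are drawn anywhere along the route (or within ``arc_range_m``)
    with a lateral jitter, so test pixels never coincide with acquisition
    pixels; gazes are uniform within ``gaze_halfwidth_deg`` of the goal
    bearing so the goal sector is well sampled.
    """
    protocol = protocol or desk_protocol()
    rng = np.random.default_rng(seed)
    lo, hi = arc_range_m if arc_range_m is not None else (0.0, trajectory.length)
    goal = np.asarray(world.goal)
    positions, gazes, arcs = [], [], []
    for _ in range(n):
        s = rng.uniform(lo, hi)
        base = trajectory.position_at(s)
        d = trajectory.direction_at(s)
        perp = np.array([d[1], -d[0]])
        pos = base + rng.normal(0.0, lateral_jitter_m) * perp
        bearing = bearing_to_target(pos, goal)
        gaze = (bearing + rng.uniform(-gaze_halfwidth_deg, gaze_halfwidth_deg)) % 360.0
        positions.append(pos)
        gazes.append(gaze)
        arcs.append(float(s))
    positions = np.asarray(positions)
    gazes = np.asarray(gazes)
    labels = np.asarray(relative_gaze(gazes, bearing_to_target(positions, goal)))
    images = np.empty((n, protocol.resolution, protocol.resolution, 2), dtype=np.float32)
    for i in range(n):
        images[i] = _render_degraded(world, positions[i], gazes[i], protocol)
    return Dataset(
        images=images,
        positions=positions,
        gazes=gazes,
        labels=labels,
        arc_m=np.asarray(arcs),
        split=np.full(n, "test", dtype="U8"),
        provenance={"seed": seed, "kind": "fresh_test_views"},
    )


def default_exclusion_ranges(trajectory: Trajectory, fraction: float = 0.23,
                             margin_m: float = 1_050.0) -> tuple[tuple[float, float], tuple[float, float]]:
    """A contiguous mid-route exclusion window of ``fraction`` of the arc
    length, tested ``margin_m`` inside on both sides (>= 1 km)."""
    L = trajectory.length
    window = fraction * L
    e0 = 0.40 * L
    e1 = e0 + window
    return (e0, e1), (e0 + margin_m, e1 - margin_m)


def experiment_full_route(seed: int = 0, world: World | None = None, trajectory: Trajectory | None = None,
                          dataset: Dataset | None = None, epochs: int = DESK_EPOCHS,
                          n_test: int = 600) -> tuple[TrainedModel, ErrorSummary, Dataset]:
    """Train on the whole route; evaluate the +-45 degree goal-sector error
    on freshly rendered jittered views."""
    world = world or default_world(child_seed(seed, "world"))
    trajectory = trajectory or default_trajectory(world, child_seed(seed, "trajectory"))
    if dataset is None:
        dataset = make_route_dataset(world, trajectory, child_seed(seed, "acquire"))
    model = build_model(desk_arch(dataset.images.shape[1]), seed=child_seed(seed, "init"))
    train_model(model, dataset, desk_hyper(child_seed(seed, "train"), epochs))
    test = fresh_test_views(world, trajectory, n_test, child_seed(seed, "test_views"))
    summary = sector_error(model, test)
    return model, summary, test


def experiment_generalization(seed: int = 0, world: World | None = None, trajectory: Trajectory | None = None,
                              dataset: Dataset | None = None, epochs: int = DESK_EPOCHS) -> tuple[TrainedModel, ErrorSummary]:
    """Excluded-segment protocol: drop a contiguous ~23% arc window from
    training, test only >= 1 km inside it, same hyperparameters."""
    world = world or default_world(child_seed(seed, "world"))
    trajectory = trajectory or default_trajectory(world, child_seed(seed, "trajectory"))
    if dataset is None:
        dataset = make_route_dataset(world, trajectory, child_seed(seed, "acquire"))
    exclude, test_range = default_exclusion_ranges(trajectory)
    train, test = split_exclude_segment(dataset, trajectory, exclude, test_range)
    model = build_model(desk_arch(dataset_resolution(dataset)), seed=child_seed(seed, "init"))
    train_model(model, train, desk_hyper(child_seed(seed, "train"), epochs))
    summary = sector_error(model, test)
    return model, summary


def dataset_resolution(dataset: Dataset) -> int:
    return int(dataset.images.shape[1])


def experiment_sim_success(seed: int = 0, world: World | None = None, trajectory: Trajectory | None = None,
                           runs_per_estimator: int = 50, config: SimConfig | None = None):
    """Closed-loop success with two noise-calibrated oracle estimators
    (wrapped-normal sd = mean error * sqrt(pi/2)); returns the batch result
    whose pooled rate is the headline success percentage."""
    world = world or default_world(child_seed(seed, "world"))
    trajectory = trajectory or default_trajectory(world, child_seed(seed, "trajectory"))
    estimators = [
        make_noisy_oracle(world, sd_for_mean_abs_error(m), seed=child_seed(seed, f"oracle{i}"))
        for i, m in enumerate(REFERENCE_MEAN_ERRORS)
    ]
    return run_batch(world, trajectory, estimators, runs_per_estimator, config or SimConfig(),
                     seed=child_seed(seed, "simulate"))
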