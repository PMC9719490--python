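"""Emulated aerial acquisition protocol over a synthetic route.

Reproduces the structure of a drone survey of a commuting bat's visual
world: full 360-degree rotations at stops every 250 m along the route,
extra between-stop views with a gaze bias toward the goal, lateral zig-zag
of the acquisition position, image degradation (bicubic downsampling to a
square two-channel image), an excluded-segment train/test split for spatial
generalisation, horizontal stripe occlusion, and off-route 360-degree probe
points 2-5 km from the route.

Every sample's label is the signed angle of its gaze relative to the goal
bearing at its position, recomputable exactly from the stored geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize

from .angles import bearing_to_target, relative_gaze, wrap_signed
from .errors import PlacementError, ProtocolError, SplitError
from .render import RenderConfig, render_view
from .trajectory import Trajectory
from .world import World

__all__ = [
    "ProtocolConfig",
    "Dataset",
    "ProbeSet",
    "sample_route_views",
    "degrade_image",
    "split_exclude_segment",
    "stripe_occlude",
    "sample_offroute_probes",
    "save_dataset",
    "load_dataset",
]

_SPLIT_CODES = {"train": 0, "test": 1, "excluded": 2}
_SPLIT_NAMES = {v: k for k, v in _SPLIT_CODES.items()}


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition protocol parameters (distances in metres, angles degrees)."""

    stop_spacing_m: float = 250.0
    rotation_step_deg: float = 5.0
    between_spacing_m: float = 125.0
    views_per_between: int = 2
    goal_bias_weight: float = 0.5    # mixture weight of the goal-facing component
    goal_bias_sd_deg: float = 40.0   # wrapped-normal sd of that component
    zigzag_amplitude_m: float = 100.0
    zigzag_period_m: float = 1_000.0
    position_jitter_m: float = 15.0
    resolution: int = 64
    supersample: int = 2             # render at supersample*resolution, then degrade
    channel_indices: tuple[int, int] = (0, 1)


@dataclass
class Dataset:
    """A labelled collection of rendered views with full provenance.

    ``arc_m`` records the along-route arc length at which each view was
    acquired (the lateral zig-zag offsets do not alter this bookkeeping);
    it drives the excluded-segment split.
    """

    images: np.ndarray       # (N, H, W, 2) float32 in [0, 1]
    positions: np.ndarray    # (N, 2) metres
    gazes: np.ndarray        # (N,) absolute azimuth [0, 360)
    labels: np.ndarray       # (N,) signed relative gaze [-180, 180)
    arc_m: np.ndarray        # (N,) acquisition arc length
    split: np.ndarray        # (N,) unicode tags from {train, test, excluded}
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray, split_tag: str | None = None) -> "Dataset":
        split = self.split[mask].copy()
        if split_tag is not None:
            split[:] = split_tag
        return Dataset(
            images=self.images[mask],
            positions=self.positions[mask],
            gazes=self.gazes[mask],
            labels=self.labels[mask],
            arc_m=self.arc_m[mask],
            split=split,
            provenance=dict(self.provenance),
        )


@dataclass
class ProbeSet:
    """All-around views at a single off-route probe point."""

    center_position: np.ndarray  # (2,)
    gazes: np.ndarray            # (M,) absolute azimuths covering [0, 360)
    images: np.ndarray           # (M, H, W, 2)
    labels: np.ndarray           # (M,) signed relative gazes
    bearing_deg: float           # goal bearing from the centre
    min_route_distance_m: float

    def __len__(self) -> int:
        return len(self.gazes)


def _render_degraded(world: World, position, gaze: float, protocol: ProtocolConfig) -> np.ndarray:
    render_cfg = RenderConfig(resolution=protocol.resolution * protocol.supersample)
    raw = render_view(world, position, gaze, render_cfg)
    if protocol.supersample == 1:
        return raw
    return degrade_image(raw, protocol.resolution, protocol.channel_indices)


def sample_route_views(
    world: World, trajectory: Trajectory, protocol: ProtocolConfig | None = None, seed: int = 0
) -> Dataset:
    """Acquire a labelled route dataset under the stop-and-rotate protocol.

    Stops every ``stop_spacing_m`` with a full rotation at
    ``rotation_step_deg`` spacing; between stops, extra views whose gaze is
    drawn from a goal-facing-biased mixture; acquisition positions zig-zag
    laterally around the route.
    """
    protocol = protocol or ProtocolConfig()
    if protocol.stop_spacing_m <= 0:
        raise ProtocolError("stop_spacing_m must be positive")
    if protocol.stop_spacing_m > trajectory.length:
        raise ProtocolError(
            f"stop_spacing_m={protocol.stop_spacing_m} exceeds route length {trajectory.length:.0f} m"
        )
    rng = np.random.default_rng(seed)
    goal = np.asarray(world.goal)

    positions, gazes, arcs = [], [], []

    def lateral_offset(s: float) -> float:
        return protocol.zigzag_amplitude_m * np.sin(2.0 * np.pi * s / protocol.zigzag_period_m)

    def acquisition_position(s: float) -> np.ndarray:
        base = trajectory.position_at(s)
        d = trajectory.direction_at(s)
        perp = np.array([d[1], -d[0]])
        jitter = rng.normal(0.0, protocol.position_jitter_m, size=2)
        return base + lateral_offset(s) * perp + jitter

    stops = np.arange(0.0, trajectory.length + 1e-6, protocol.stop_spacing_m)
    n_rot = int(round(360.0 / protocol.rotation_step_deg))
    for s in stops:
        pos = acquisition_position(float(s))
        gaze0 = rng.uniform(0.0, protocol.rotation_step_deg)
        for k in range(n_rot):
            positions.append(pos)
            gazes.append((gaze0 + k * protocol.rotation_step_deg) % 360.0)
            arcs.append(float(s))

    if protocol.views_per_between > 0 and protocol.between_spacing_m > 0:
        mids = np.arange(protocol.between_spacing_m, trajectory.length, protocol.stop_spacing_m)
        for s in mids:
            pos = acquisition_position(float(s))
            bearing = bearing_to_target(pos, goal)
            for _ in range(protocol.views_per_between):
                if rng.random() < protocol.goal_bias_weight:
                    gaze = (bearing + rng.normal(0.0, protocol.goal_bias_sd_deg)) % 360.0
                else:
                    gaze = rng.uniform(0.0, 360.0)
                positions.append(pos)
                gazes.append(float(gaze))
                arcs.append(float(s))

    positions = np.asarray(positions)
    gazes = np.asarray(gazes)
    arcs = np.asarray(arcs)
    if len(np.unique(np.round(np.column_stack([positions, gazes[:, None]]), 9), axis=0)) != len(gazes):
        raise ProtocolError("duplicate (position, gaze) pairs in acquisition")
    labels = relative_gaze(gazes, bearing_to_target(positions, goal))

    images = np.empty((len(gazes), protocol.resolution, protocol.resolution, 2), dtype=np.float32)
    for i in range(len(gazes)):
        images[i] = _render_degraded(world, positions[i], gazes[i], protocol)

    return Dataset(
        images=images,
        positions=positions,
        gazes=gazes,
        labels=np.asarray(labels),
        arc_m=arcs,
        split=np.full(len(gazes), "train", dtype="U8"),
        provenance={"seed": seed, "protocol": vars(protocol) | {}, "world_seed": world.seed},
    )


def degrade_image(image: np.ndarray, target_resolution: int, channel_indices: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Bicubic downsampling to a square two-channel image in [0, 1].

    Degradation only: requesting a resolution above the input raises.
    Applying the same target twice is a no-op after the first application.
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    if H < target_resolution or W < target_resolution:
        raise ValueError("degrade_image only downsamples; target exceeds input size")
    ci = tuple(channel_indices)
    if len(ci) != 2 or max(ci) >= image.shape[2]:
        raise ValueError("channel_indices must name two valid channels")
    selected = image[:, :, list(ci)]
    if H == target_resolution and W == target_resolution:
        return np.clip(selected, 0.0, 1.0).astype(np.float32)
    out = resize(
        selected.astype(np.float64),
        (target_resolution, target_resolution),
        order=3,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def split_exclude_segment(
    dataset: Dataset,
    trajectory: Trajectory,
    exclude_range_m: tuple[float, float],
    test_range_m: tuple[float, float],
    min_gap_m: float = 1_000.0,
) -> tuple[Dataset, Dataset]:
    """Excluded-segment split for spatial generalisation.

    Training drops every sample whose acquisition arc length lies inside
    ``exclude_range_m``; testing keeps only samples inside ``test_range_m``,
    which must sit at least ``min_gap_m`` inside the excluded window on both
    sides.  The realised euclidean train-test gap is asserted and reported.
    """
    e0, e1 = exclude_range_m
    t0, t1 = test_range_m
    if e1 < e0 or t1 < t0:
        raise SplitError("ranges must be increasing intervals")
    if e0 == e1:  # degenerate: nothing excluded, nothing tested
        return dataset.subset(np.ones(len(dataset), bool), "train"), dataset.subset(
            np.zeros(len(dataset), bool), "test"
        )
    if t0 - e0 < min_gap_m or e1 - t1 < min_gap_m:
        raise SplitError(
            f"test range must sit >= {min_gap_m} m inside the excluded range "
            f"(margins {t0 - e0:.0f} and {e1 - t1:.0f} m)"
        )
    arc = dataset.arc_m
    train_mask = (arc < e0) | (arc > e1)
    test_mask = (arc >= t0) & (arc <= t1)
    train = dataset.subset(train_mask, "train")
    test = dataset.subset(test_mask, "test")
    if len(train) and len(test):
        gap = _min_pairwise_distance(train.positions, test.positions)
        if gap < min_gap_m:
            raise SplitError(f"measured train-test gap {gap:.1f} m is below the {min_gap_m} m requirement")
        train.provenance["measured_gap_m"] = gap
        test.provenance["measured_gap_m"] = gap
    return train, test


def _min_pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    best = np.inf
    step = 2048
    for i in range(0, len(a), step):
        d = a[i : i + step, None, :] - b[None, :, :]
        best = min(best, float(np.sqrt((d**2).sum(-1)).min()))
    return best


def stripe_occlude(image: np.ndarray, which_third: str) -> np.ndarray:
    """Zero one horizontal third of an image.

    Heights not divisible by 3 are truncated at the bottom first (a
    deterministic, documented rule), so the output height is ``3*(H//3)``.
    """
    if which_third not in ("top", "middle", "bottom"):
        raise ValueError(f"which_third must be top/middle/bottom, got {which_third!r}")
    image = np.asarray(image)
    third = image.shape[0] // 3
    out = image[: 3 * third].copy()
    k = ("top", "middle", "bottom").index(which_third)
    out[k * third : (k + 1) * third] = 0.0
    return out


def sample_offroute_probes(
    world: World,
    trajectory: Trajectory,
    n_points: int = 9,
    distance_range_m: tuple[float, float] = (2_000.0, 5_000.0),
    seed: int = 0,
    gaze_step_deg: float = 1.0,
    protocol: ProtocolConfig | None = None,
    max_tries: int = 2_000,
) -> list[ProbeSet]:
    """Probe points with full 360-degree view coverage, each at a minimum
    euclidean distance to the route inside ``distance_range_m``."""
    lo, hi = distance_range_m
    if lo <= 0 or hi < lo:
        raise ValueError("distance_range_m must be a positive increasing interval")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(seed)
    goal = np.asarray(world.goal)
    probes: list[ProbeSet] = []
    tries = 0
    while len(probes) < n_points:
        tries += 1
        if tries > max_tries:
            raise PlacementError(f"could not place {n_points} probes in {max_tries} tries")
        s = rng.uniform(0.0, trajectory.length)
        side = 1.0 if rng.random() < 0.5 else -1.0
        d_target = rng.uniform(lo, hi)
        base = trajectory.position_at(s)
        t = trajectory.direction_at(s)
        center = base + side * d_target * np.array([t[1], -t[0]])
        d_actual = trajectory.min_distance_to(center)
        if not lo <= d_actual <= hi:
            continue
        gazes = np.arange(0.0, 360.0, gaze_step_deg)
        bearing = bearing_to_target(center, goal)
        labels = wrap_signed(gazes - bearing)
        images = np.empty((len(gazes), protocol.resolution, protocol.resolution, 2), dtype=np.float32)
        for i, g in enumerate(gazes):
            images[i] = _render_degraded(world, center, float(g), protocol)
        probes.append(
            ProbeSet(
                center_position=center,
                gazes=gazes,
                images=images,
                labels=np.asarray(labels),
                bearing_deg=float(bearing),
                min_route_distance_m=float(d_actual),
            )
        )
    return probes


# ---------------------------------------------------------------------------
# chunked array-container IO

def save_dataset(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=dataset.images, chunks=True, compression="gzip")
        fh.create_dataset("positions", data=dataset.positions)
        fh.create_dataset("gazes", data=dataset.gazes)
        fh.create_dataset("labels", data=dataset.labels)
        fh.create_dataset("arc_m", data=dataset.arc_m)
        fh.create_dataset("split", data=np.vectorize(_SPLIT_CODES.get)(dataset.split).astype(np.int8))
        fh.attrs["provenance"] = json.dumps(dataset.provenance, default=str)


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as fh:
        split = np.vectorize(_SPLIT_NAMES.get)(fh["split"][:]).astype("U8")
        return Dataset(
            images=fh["images"][:],
            positions=fh["positions"][:],
            gazes=fh["gazes"][:],
            labels=fh["labels"][:],
            arc_m=fh["arc_m"][:],
            split=split,
            provenance=json.loads(fh.attrs["provenance"]),
        )
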