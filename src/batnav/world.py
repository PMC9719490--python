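"""Seeded synthetic nocturnal landscapes.

A ``World`` is a flat plane (metres; x=east, y=north) carrying point/extended
light sources, a ground-texture seed, a two-parameter sky gradient, an origin
("cave") and a goal ("target tree") 17.2 km away by default.  The default
layout emulates a nocturnal commute corridor: a handful of bright, visually
distinct towns scattered along and beyond the route, plus one dominant city
well off the origin-goal axis, so that brightest-direction steering
(phototaxis) never points at the goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .angles import bearing_to_target
from .errors import ConfigurationError

__all__ = [
    "LightSource",
    "WorldConfig",
    "World",
    "DriftConfig",
    "LightProfile",
    "build_world",
    "perturb_world",
    "angular_light_profile",
    "validate_world",
    "save_world",
    "load_world",
]


@dataclass(frozen=True)
class LightSource:
    """One light blob: position (m), peak radiance (arbitrary nonneg units),
    spatial extent (m), and per-channel weights summing to <= 1."""

    position: tuple[float, float]
    peak_radiance: float
    extent_m: float
    channel_weights: tuple[float, float]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic landscape generator.

    Distances in metres, radiances in arbitrary units with the ordinary-source
    median at ``radiance_median``.  The dominant city is placed
    ``city_lateral_m`` off the origin->goal axis with radiance
    ``city_radiance_factor`` times the median of the ordinary sources.
    """

    goal_distance_m: float = 17_200.0
    goal_bearing_deg: float = 315.0
    n_light_sources: int = 24
    radiance_median: float = 1.0
    radiance_log_sigma: float = 0.6
    extent_range_m: tuple[float, float] = (150.0, 900.0)
    scatter_lateral_range_m: tuple[float, float] = (1_500.0, 10_000.0)
    forward_fraction: float = 0.35
    forward_along_range_m: tuple[float, float] = (-2_000.0, 9_000.0)
    forward_lateral_m: float = 7_000.0
    city_radiance_factor: float = 25.0
    city_along_frac: float = 0.45
    city_lateral_m: float = -6_500.0
    city_extent_m: float = 1_200.0
    sky_top: float = 0.06
    sky_horizon: float = 0.14
    min_city_axis_offset_m: float = 2_000.0


@dataclass(frozen=True)
class World:
    """An immutable synthetic landscape (value-comparable and serialisable)."""

    light_sources: tuple[LightSource, ...]
    ground_texture_seed: int
    sky_gradient_params: tuple[float, float]
    origin: tuple[float, float]
    goal: tuple[float, float]
    seed: int
    config: WorldConfig = field(default_factory=WorldConfig)

    @property
    def goal_distance(self) -> float:
        return float(math.hypot(self.goal[0] - self.origin[0], self.goal[1] - self.origin[1]))

    @property
    def goal_bearing(self) -> float:
        return bearing_to_target(self.origin, self.goal)

    @property
    def dominant_source(self) -> LightSource:
        return max(self.light_sources, key=lambda s: s.peak_radiance)


@dataclass(frozen=True)
class DriftConfig:
    """Year-to-year scene drift: each ordinary source is independently
    modified with probability ``fraction`` (moved, re-lit, or replaced)."""

    fraction: float = 0.2
    move_sd_m: float = 500.0
    radiance_log_sigma: float = 0.3


@dataclass(frozen=True)
class LightProfile:
    """Angular distribution of light mass around a point: fraction of total
    radiance-weighted mass per azimuth bin, within ``radius_m``."""

    bin_centers_deg: np.ndarray
    fraction_of_total: np.ndarray
    radius_m: float


def _axes(bearing_deg: float) -> tuple[np.ndarray, np.ndarray]:
    b = math.radians(bearing_deg)
    u = np.array([math.sin(b), math.cos(b)])   # along-track unit vector
    v = np.array([math.cos(b), -math.sin(b)])  # perpendicular (to the right)
    return u, v


def _validate_config(config: WorldConfig) -> None:
    if config.goal_distance_m <= 0:
        raise ConfigurationError("goal_distance_m must be positive")
    if config.n_light_sources < 1:
        raise ConfigurationError("n_light_sources must be at least 1")
    if config.radiance_median <= 0:
        raise ConfigurationError("radiance_median must be positive")
    lo, hi = config.extent_range_m
    if lo <= 0 or hi < lo:
        raise ConfigurationError("extent_range_m must be a positive increasing interval")
    if not 0.0 <= config.forward_fraction <= 1.0:
        raise ConfigurationError("forward_fraction must lie in [0, 1]")


def _channel_weights(rng: np.random.Generator) -> tuple[float, float]:
    # Two correlated, non-identical channels: nearly monochromatic sources.
    w0 = rng.uniform(0.35, 0.48)
    asym = rng.uniform(-0.12, 0.12)
    return (round(w0 * (1 + asym), 6), round(w0 * (1 - asym), 6))


def build_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate a seeded synthetic landscape satisfying all World invariants.

    Identical (config, seed) pairs yield identical worlds.
    """
    config = config or WorldConfig()
    _validate_config(config)
    rng = np.random.default_rng(seed)
    u, v = _axes(config.goal_bearing_deg)
    origin = np.zeros(2)
    goal = origin + config.goal_distance_m * u

    n = config.n_light_sources
    n_forward = int(round(config.forward_fraction * n))
    n_scatter = n - n_forward
    sources: list[LightSource] = []
    for _ in range(n_scatter):
        s = rng.uniform(0.0, config.goal_distance_m)
        side = 1.0 if rng.random() < 0.5 else -1.0
        lat = side * rng.uniform(*config.scatter_lateral_range_m)
        pos = origin + s * u + lat * v
        sources.append(
            LightSource(
                position=(float(pos[0]), float(pos[1])),
                peak_radiance=float(config.radiance_median * np.exp(rng.normal(0.0, config.radiance_log_sigma))),
                extent_m=float(rng.uniform(*config.extent_range_m)),
                channel_weights=_channel_weights(rng),
            )
        )
    for _ in range(n_forward):
        s = config.goal_distance_m + rng.uniform(*config.forward_along_range_m)
        lat = rng.uniform(-config.forward_lateral_m, config.forward_lateral_m)
        pos = origin + s * u + lat * v
        sources.append(
            LightSource(
                position=(float(pos[0]), float(pos[1])),
                peak_radiance=float(config.radiance_median * np.exp(rng.normal(0.0, config.radiance_log_sigma))),
                extent_m=float(rng.uniform(*config.extent_range_m)),
                channel_weights=_channel_weights(rng),
            )
        )

    median_radiance = float(np.median([s.peak_radiance for s in sources])) if sources else config.radiance_median
    city_pos = origin + config.city_along_frac * config.goal_distance_m * u + config.city_lateral_m * v
    sources.append(
        LightSource(
            position=(float(city_pos[0]), float(city_pos[1])),
            peak_radiance=float(config.city_radiance_factor * median_radiance),
            extent_m=float(config.city_extent_m),
            channel_weights=(0.46, 0.44),
        )
    )

    world = World(
        light_sources=tuple(sources),
        ground_texture_seed=int(rng.integers(0, 2**31 - 1)),
        sky_gradient_params=(config.sky_top, config.sky_horizon),
        origin=(0.0, 0.0),
        goal=(float(goal[0]), float(goal[1])),
        seed=seed,
        config=config,
    )
    validate_world(world)
    return world


def _axis_offset(world: World, position: tuple[float, float]) -> float:
    """Perpendicular distance of a point from the origin->goal axis."""
    u, v = _axes(world.goal_bearing)
    p = np.asarray(position) - np.asarray(world.origin)
    return float(abs(p @ v))


def validate_world(world: World) -> None:
    """Check all World invariants; raises ConfigurationError on violation."""
    if world.goal == world.origin:
        raise ConfigurationError("goal must differ from origin")
    if not world.light_sources:
        raise ConfigurationError("light_sources must be non-empty")
    radiances = np.array([s.peak_radiance for s in world.light_sources])
    if np.any(radiances < 0):
        raise ConfigurationError("peak_radiance must be nonnegative")
    dom = world.dominant_source
    others = [s.peak_radiance for s in world.light_sources if s is not dom]
    if others and dom.peak_radiance <= 10.0 * float(np.median(others)):
        raise ConfigurationError("peak_radiance of the dominant city must exceed 10x the median source")
    if _axis_offset(world, dom.position) < world.config.min_city_axis_offset_m:
        raise ConfigurationError("city_lateral_m: dominant city must sit off the origin->goal axis")
    for s in world.light_sources:
        if sum(s.channel_weights) > 1.0 + 1e-9:
            raise ConfigurationError("channel_weights must sum to at most 1")


def perturb_world(world: World, drift: DriftConfig | None = None, seed: int = 0) -> World:
    """Year-to-year drift: move/re-light/replace a seeded random fraction of
    ordinary sources.  The dominant city is always retained unchanged (it is
    the stable landmark the generalisation analysis leans on).  Drift
    fraction 0 returns a world equal to the input.
    """
    drift = drift or DriftConfig()
    if not 0.0 <= drift.fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dom = world.dominant_source
    u, v = _axes(world.goal_bearing)
    new_sources: list[LightSource] = []
    for src in world.light_sources:
        # Draw a fixed number of variates per source so the stream alignment
        # does not depend on which sources are modified.
        modify = rng.random() < drift.fraction
        action = rng.integers(0, 3)
        dxy = rng.normal(0.0, drift.move_sd_m, size=2)
        rad_factor = float(np.exp(rng.normal(0.0, drift.radiance_log_sigma)))
        s_new = rng.uniform(0.0, world.goal_distance)
        lat_new = (1.0 if rng.random() < 0.5 else -1.0) * rng.uniform(*world.config.scatter_lateral_range_m)
        if src is dom or not modify:
            new_sources.append(src)
            continue
        if action == 0:  # move
            pos = np.asarray(src.position) + dxy
            new_sources.append(replace(src, position=(float(pos[0]), float(pos[1]))))
        elif action == 1:  # re-light
            new_sources.append(replace(src, peak_radiance=float(src.peak_radiance * rad_factor)))
        else:  # replace: new building cluster elsewhere in the corridor
            pos = np.asarray(world.origin) + s_new * u + lat_new * v
            new_sources.append(replace(src, position=(float(pos[0]), float(pos[1]))))
    return replace(world, light_sources=tuple(new_sources))


def angular_light_profile(
    world: World, center, radius_m: float = 15_000.0, n_bins: int = 36
) -> LightProfile:
    """Azimuthal distribution of light mass within ``radius_m`` of ``center``.

    Each source contributes mass ``peak_radiance * extent_m**2`` (radiance
    times emitting area) in the bin of its azimuth from ``center``.  Bin k is
    centred at ``k * 360/n_bins`` so that map north falls at a bin centre.
    """
    if radius_m <= 0:
        raise ConfigurationError("radius_m must be positive")
    if n_bins < 4:
        raise ConfigurationError("n_bins must be at least 4")
    center = np.asarray(center, dtype=float)
    width = 360.0 / n_bins
    mass = np.zeros(n_bins)
    found = False
    for src in world.light_sources:
        pos = np.asarray(src.position)
        d = float(np.hypot(*(pos - center)))
        if d == 0.0 or d > radius_m:
            continue
        found = True
        az = bearing_to_target(center, src.position)
        k = int(np.floor(((az + width / 2.0) % 360.0) / width))
        mass[k] += src.peak_radiance * src.extent_m**2
    if not found or mass.sum() <= 0:
        raise ConfigurationError(f"no light sources within {radius_m} m of center; profile undefined")
    centers = np.arange(n_bins) * width
    return LightProfile(bin_centers_deg=centers, fraction_of_total=mass / mass.sum(), radius_m=float(radius_m))


# ---------------------------------------------------------------------------
# plain-text serialisation

def save_world(world: World, path) -> None:
    """Write a world as a YAML document (plain text, round-trippable)."""
    doc = {
        "seed": world.seed,
        "ground_texture_seed": world.ground_texture_seed,
        "sky_gradient_params": list(world.sky_gradient_params),
        "origin": list(world.origin),
        "goal": list(world.goal),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(world.config).items()},
        "light_sources": [
            {
                "position": list(s.position),
                "peak_radiance": s.peak_radiance,
                "extent_m": s.extent_m,
                "channel_weights": list(s.channel_weights),
            }
            for s in world.light_sources
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_world(path) -> World:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg_raw = doc["config"]
    defaults = WorldConfig()
    cfg = WorldConfig(**{
        k: (tuple(v) if isinstance(getattr(defaults, k), tuple) else v) for k, v in cfg_raw.items()
    })
    sources = tuple(
        LightSource(
            position=tuple(s["position"]),
            peak_radiance=s["peak_radiance"],
            extent_m=s["extent_m"],
            channel_weights=tuple(s["channel_weights"]),
        )
        for s in doc["light_sources"]
    )
    return World(
        light_sources=sources,
        ground_texture_seed=doc["ground_texture_seed"],
        sky_gradient_params=tuple(doc["sky_gradient_params"]),
        origin=tuple(doc["origin"]),
        goal=tuple(doc["goal"]),
        seed=doc["seed"],
        config=cfg,
    )
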