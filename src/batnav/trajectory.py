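"""Commute trajectories from the origin ("cave") to the goal ("target tree").

The default geometry is a gently meandering path: the straight origin->goal
chord plus a smooth sinusoidal lateral offset whose envelope pins both
endpoints.  Curvature stays mild (consecutive-segment heading changes well
under the 15 degree bound), as expected of a commuting flight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .angles import angular_difference
from .errors import GenerationError
from .world import World, _axes

__all__ = ["TrajectoryConfig", "Trajectory", "make_trajectory", "save_trajectory", "load_trajectory"]


@dataclass(frozen=True)
class TrajectoryConfig:
    waypoint_spacing_m: float = 40.0
    lateral_amplitude_m: float = 300.0
    lateral_periods: float = 2.5
    max_turn_deg: float = 15.0


class Trajectory:
    """An ordered polyline of waypoints with cumulative arc length.

    Provides arc-length parameterised access: ``position_at(s)`` and
    ``direction_at(s)`` interpolate linearly between waypoints.
    """

    def __init__(self, waypoints: np.ndarray):
        self.waypoints = np.asarray(waypoints, dtype=float)
        seg = np.diff(self.waypoints, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        self.cum_length = np.concatenate([[0.0], np.cumsum(seg_len)])
        self._line = LineString(self.waypoints)

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def position_at(self, s):
        """Planar position at arc length ``s`` (clipped to [0, length])."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self.cum_length, self.waypoints[:, 0])
        y = np.interp(s, self.cum_length, self.waypoints[:, 1])
        return np.stack([x, y], axis=-1)

    def direction_at(self, s) -> np.ndarray:
        """Unit tangent of the segment containing arc length ``s``."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.clip(np.searchsorted(self.cum_length, s, side="right") - 1, 0, len(self.waypoints) - 2))
        seg = self.waypoints[i + 1] - self.waypoints[i]
        return seg / np.hypot(*seg)

    def min_distance_to(self, point) -> float:
        """Shortest euclidean distance from a point to the polyline."""
        return float(self._line.distance(Point(*np.asarray(point, dtype=float))))

    def headings_deg(self) -> np.ndarray:
        seg = np.diff(self.waypoints, axis=0)
        return np.degrees(np.arctan2(seg[:, 0], seg[:, 1])) % 360.0


def make_trajectory(world: World, config: TrajectoryConfig | None = None, seed: int = 0) -> Trajectory:
    """Build a seeded origin->goal trajectory for ``world``.

    Raises GenerationError if the requested lateral geometry would bend the
    path harder than ``max_turn_deg`` between consecutive segments.
    """
    config = config or TrajectoryConfig()
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    u, v = _axes(world.goal_bearing)
    D = world.goal_distance
    n = int(np.ceil(D / config.waypoint_spacing_m)) + 1
    tau = np.linspace(0.0, 1.0, n)
    lateral = (
        config.lateral_amplitude_m
        * np.sin(2.0 * np.pi * config.lateral_periods * tau + phase)
        * np.sin(np.pi * tau)
    )
    pts = np.asarray(world.origin) + tau[:, None] * D * u[None, :] + lateral[:, None] * v[None, :]
    traj = Trajectory(pts)
    headings = traj.headings_deg()
    turns = angular_difference(headings[1:], headings[:-1])
    if np.max(turns, initial=0.0) > config.max_turn_deg:
        raise GenerationError(
            f"lateral geometry infeasible: max segment turn {np.max(turns):.1f} deg "
            f"exceeds the {config.max_turn_deg} deg bound"
        )
    return traj


def save_trajectory(traj: Trajectory, path) -> None:
    """CSV waypoint table with columns index, x_m, y_m, cum_len_m."""
    df = pd.DataFrame(
        {
            "index": np.arange(len(traj.waypoints)),
            "x_m": traj.waypoints[:, 0],
            "y_m": traj.waypoints[:, 1],
            "cum_len_m": traj.cum_length,
        }
    )
    df.to_csv(path, index=False)


def load_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df[["x_m", "y_m"]].to_numpy())
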