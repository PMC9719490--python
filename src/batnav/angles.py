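"""Circular angle arithmetic on the single compass convention used package-wide.

Absolute azimuths are degrees clockwise in [0, 360) with 0 = map north (+y
axis).  Relative angles (a gaze relative to the goal bearing, a prediction
error) are signed degrees in [-180, 180).  Every function accepts scalars or
arrays and wraps its inputs, so callers never normalise angles themselves.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "wrap_signed",
    "wrap_unsigned",
    "angular_difference",
    "signed_error",
    "bearing_to_target",
    "relative_gaze",
]


def _like_input(out: np.ndarray, *inputs):
    if all(np.ndim(x) == 0 for x in inputs):
        return float(out)
    return out


def wrap_signed(angle_deg):
    """Wrap any angle to the signed interval [-180, 180)."""
    out = (np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0
    return _like_input(out, angle_deg)


def wrap_unsigned(angle_deg):
    """Wrap any angle to [0, 360)."""
    out = np.asarray(angle_deg, dtype=float) % 360.0
    return _like_input(out, angle_deg)


def angular_difference(a1_deg, a2_deg):
    """Magnitude of the shorter arc between two angles, in [0, 180].

    Equals ``min(|a1 - a2|, 360 - |a1 - a2|)``.
    """
    out = np.abs(np.asarray(wrap_signed(np.asarray(a1_deg, dtype=float) - np.asarray(a2_deg, dtype=float))))
    return _like_input(out, a1_deg, a2_deg)


def signed_error(pred_deg, label_deg):
    """Signed companion of :func:`angular_difference`: wrap(pred - label).

    Positive means the prediction is clockwise of the label.
    """
    out = wrap_signed(np.asarray(pred_deg, dtype=float) - np.asarray(label_deg, dtype=float))
    return _like_input(np.asarray(out), pred_deg, label_deg)


def bearing_to_target(position, goal):
    """Clockwise azimuth of ``goal`` as seen from ``position``, in [0, 360).

    Positions are planar (x=east, y=north) metres.  Raises if the two
    coincide (the bearing is undefined there).
    """
    position = np.asarray(position, dtype=float)
    goal = np.asarray(goal, dtype=float)
    d = goal - position
    dx = d[..., 0]
    dy = d[..., 1]
    if np.any((dx == 0.0) & (dy == 0.0)):
        raise ConfigurationError("bearing_to_target: position coincides with goal; bearing undefined")
    out = np.degrees(np.arctan2(dx, dy)) % 360.0
    if out.ndim == 0:
        return float(out)
    return out


def relative_gaze(gaze_azimuth_deg, bearing_deg):
    """Signed angle of a gaze relative to a bearing: wrap(gaze - bearing).

    Zero iff the gaze points exactly at the goal; this is the regression
    label of every view sample.
    """
    return signed_error(gaze_azimuth_deg, bearing_deg)
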