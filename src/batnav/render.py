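"""Deterministic panoramic renderer for synthetic night scenes.

Each view is a square two-channel image spanning an 80 degree horizontal
field of view, composed of three vertical bands:

* top third   - sky: a pure vertical luminance gradient (no azimuthal
  information, by construction);
* middle third - horizon: Gaussian blobs of the light sources, placed by
  perspective (pixel column is linear in the signed angle between the source
  azimuth and the gaze), with intensity scaling with peak radiance and
  decaying with distance;
* bottom third - ground: a position-locked value-noise texture plus a broad
  glow from nearby sources.

Confining all horizon information to the middle band makes the
stripe-occlusion analysis (which band carries the navigation signal) a
designed, testable property of the scene model rather than an accident.
The renderer is a pure function: identical inputs give identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap_signed
from .world import World

__all__ = ["RenderConfig", "render_view", "source_pixel_column"]


@dataclass(frozen=True)
class RenderConfig:
    resolution: int = 64
    fov_deg: float = 80.0
    view_height_m: float = 100.0
    # sky band
    sky_channel_weights: tuple[float, float] = (1.0, 0.85)
    # horizon band
    attenuation_halfdist_m: float = 8_000.0
    min_blur_deg: float = 1.2
    gain: float = 1.0
    # ground band
    ground_base: float = 0.07
    ground_noise: float = 0.03
    ground_cell_m: float = 60.0
    ground_channel_weights: tuple[float, float] = (1.0, 0.95)
    max_ground_depression_deg: float = 30.0
    glow_gain: float = 0.35
    glow_range_m: float = 2_500.0
    glow_sigma_deg: float = 25.0


def _hash01(ix: np.ndarray, iy: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic lattice hash in [0, 1) (no global random state)."""
    h = np.sin(ix * 127.1 + iy * 311.7 + (seed % 100_000) * 0.6180339887) * 43758.5453123
    return h - np.floor(h)


def source_pixel_column(rel_angle_deg: float, width: int, fov_deg: float) -> float:
    """Analytic perspective projection: pixel column of a feature at the given
    signed angle relative to the gaze (column centres at (j+0.5)/W)."""
    return width / 2.0 + rel_angle_deg / fov_deg * width - 0.5


def render_view(world: World, position, gaze_azimuth_deg: float, config: RenderConfig | None = None) -> np.ndarray:
    """Render one view; returns a float32 array (H, W, 2) with values in [0, 1].

    Any real gaze is accepted (wrapped mod 360); the position must be finite.
    """
    config = config or RenderConfig()
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    gaze = float(gaze_azimuth_deg) % 360.0
    H = W = int(config.resolution)
    third = H // 3
    img = np.zeros((H, W, 2), dtype=np.float64)

    # column azimuths (clockwise convention: panning right increases azimuth)
    col_az = gaze + ((np.arange(W) + 0.5) / W - 0.5) * config.fov_deg

    # --- sky band: vertical gradient only
    sky_top, sky_horizon = world.sky_gradient_params
    rows_sky = np.arange(third)
    grad = sky_top + (sky_horizon - sky_top) * (rows_sky + 0.5) / max(third, 1)
    for c, wc in enumerate(config.sky_channel_weights):
        img[:third, :, c] = (grad * wc)[:, None]

    # --- horizon band: perspective-projected source blobs
    r_mid = np.arange(third, 2 * third)
    r_center = (H - 1) / 2.0
    src_pos = np.array([s.position for s in world.light_sources])
    rel = src_pos - position[None, :]
    dist = np.hypot(rel[:, 0], rel[:, 1])
    az = np.degrees(np.arctan2(rel[:, 0], rel[:, 1])) % 360.0
    atten = 1.0 / (1.0 + (dist / config.attenuation_halfdist_m) ** 2)
    extents = np.array([s.extent_m for s in world.light_sources])
    radiances = np.array([s.peak_radiance for s in world.light_sources])
    weights = np.array([s.channel_weights for s in world.light_sources])
    sigma_deg = np.maximum(config.min_blur_deg, np.degrees(np.arctan2(extents, np.maximum(dist, 1.0))))
    px_per_deg = W / config.fov_deg
    for i in range(len(src_pos)):
        if dist[i] == 0.0 or radiances[i] <= 0.0:
            continue
        delta = wrap_signed(col_az - az[i])
        if np.min(np.abs(delta)) > config.fov_deg / 2.0 + 4.0 * sigma_deg[i]:
            continue  # entirely outside the field of view
        horiz = np.exp(-0.5 * (delta / sigma_deg[i]) ** 2)
        sigma_v = max(1.2, 0.6 * sigma_deg[i] * px_per_deg)
        vert = np.exp(-0.5 * ((r_mid - r_center) / sigma_v) ** 2)
        blob = np.outer(vert, horiz) * (config.gain * radiances[i] * atten[i])
        img[third : 2 * third, :, 0] += blob * weights[i, 0]
        img[third : 2 * third, :, 1] += blob * weights[i, 1]

    # --- ground band: projected value noise + glow of nearby sources
    rows_gnd = np.arange(2 * third, H)
    if len(rows_gnd):
        frac = (rows_gnd - 2 * third + 1.0) / (H - 2 * third)
        depress = np.radians(config.max_ground_depression_deg) * frac
        ground_dist = config.view_height_m / np.tan(np.maximum(depress, 1e-3))
        az_rad = np.radians(col_az)
        ux, uy = np.sin(az_rad), np.cos(az_rad)
        qx = position[0] + ground_dist[:, None] * ux[None, :]
        qy = position[1] + ground_dist[:, None] * uy[None, :]
        noise = _hash01(np.floor(qx / config.ground_cell_m), np.floor(qy / config.ground_cell_m), world.ground_texture_seed)
        base = config.ground_base + config.ground_noise * noise
        glow = np.zeros(W)
        near = np.flatnonzero((dist > 0) & (dist < config.glow_range_m))
        for i in near:
            delta = wrap_signed(col_az - az[i])
            glow += (
                config.glow_gain
                * radiances[i]
                * (1.0 / (1.0 + (dist[i] / (0.4 * config.glow_range_m)) ** 2))
                * np.exp(-0.5 * (delta / config.glow_sigma_deg) ** 2)
            )
        for c, wc in enumerate(config.ground_channel_weights):
            img[2 * third :, :, c] = (base + glow[None, :]) * wc

    return np.clip(img, 0.0, 1.0).astype(np.float32)
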