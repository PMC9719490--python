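"""Shared fixtures: small seeded worlds, datasets and models.

Everything is generated programmatically at collection time from fixed
seeds; the heavier session fixtures (a tiny trained model) are built once
and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import batnav
from batnav import experiments
from batnav.pipeline import make_fixtures
from batnav.world import LightSource, World, WorldConfig


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def tiny_world(fixtures):
    return fixtures["world"]


@pytest.fixture(scope="session")
def tiny_trajectory(fixtures):
    return fixtures["trajectory"]


@pytest.fixture(scope="session")
def tiny_dataset(fixtures):
    return fixtures["dataset"]


def make_single_source_world(
    source_pos=(0.0, 5_000.0), radiance=5.0, extent=300.0, goal=(0.0, 2_000.0), texture_seed=11
) -> World:
    """A hand-built world with one light source (bypasses the dominant-city
    construction; used for projection-oracle and profile tests)."""
    return World(
        light_sources=(
            LightSource(position=source_pos, peak_radiance=radiance, extent_m=extent, channel_weights=(0.5, 0.45)),
        ),
        ground_texture_seed=texture_seed,
        sky_gradient_params=(0.06, 0.14),
        origin=(0.0, 0.0),
        goal=goal,
        seed=0,
        config=WorldConfig(goal_distance_m=2_000.0, n_light_sources=1),
    )


@pytest.fixture(scope="session")
def trained_tiny_model(fixtures):
    """A small network trained for a few epochs on the tiny route dataset."""
    ds = fixtures["dataset"]
    arch = batnav.ArchConfig(
        conv_blocks=((6, 3, 2), (12, 3, 2)), fc_sizes=(32, 16, 8), input_hw=ds.images.shape[1:3]
    )
    model = batnav.build_model(arch, seed=3)
    batnav.train_model(model, ds, batnav.Hyperparams(epochs=6, seed=3, lr_decay_epochs=(4,)))
    return model
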