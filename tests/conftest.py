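"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from greenfruit.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def tiny_config() -> SceneConfig:
    """A 96x96 scene config small enough for fast unit tests."""
    return SceneConfig(
        image_size=(96, 96),
        n_fruit=(2, 4),
        fruit_radius=(8, 18),
        n_leaf_occluders=(3, 6),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return generate_scene(tiny_config, np.random.default_rng(11), image_id="tiny")


@pytest.fixture(scope="session")
def tiny_scenes(tiny_config):
    rng = np.random.default_rng(23)
    return [generate_scene(tiny_config, rng, image_id=f"scene{i}") for i in range(6)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
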