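"""Shared synthetic-scene fixtures.

Everything is generated at test time from fixed seeds; there are no stored
image fixtures.  The two rendered scenes are session-scoped because
rendering dominates test cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from pecktrack import scene
from pecktrack.vision import Calibration


def two_episode_script(seed: int = 0) -> scene.KinematicScript:
    rng = np.random.default_rng(seed)
    episodes = [
        scene.make_episode(
            rng,
            [
                (1, 4.0, 20, False),
                (2, 3.5, 24, False),
                (3, 3.0, 23, False),
                (4, 2.6, 26, True),
            ],
        )
        for _ in range(2)
    ]
    return scene.make_script(rng, episodes)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, particle-free rendered scene with ground truth."""
    cfg = scene.SceneConfig(noise_sd=0.0, particle_count=0, seed=7)
    frames, truth = scene.render_sequence(cfg, two_episode_script(seed=0))
    return cfg, frames, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene with feed particles near the beak."""
    cfg = scene.SceneConfig(seed=7)
    frames, truth = scene.render_sequence(cfg, two_episode_script(seed=0))
    return cfg, frames, truth


@pytest.fixture()
def calibration():
    return Calibration(mm_per_px=0.1)
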