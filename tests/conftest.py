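"""Shared fixtures: rigs and scenes are expensive, so session-scoped."""

import numpy as np
import pytest

import thermomap as tm


@pytest.fixture(scope="session")
def identity_rig():
    return tm.make_rig("identity")


@pytest.fixture(scope="session")
def realistic_rig():
    """Realistic full-resolution rig: distortion, rotation, 47 mm baseline."""
    return tm.make_rig("realistic", seed=7)


@pytest.fixture(scope="session")
def pure_baseline_rig():
    """Zero distortion, identity rotation, pure 47 mm X baseline."""
    return tm.make_rig(
        "realistic", seed=4, baseline_mm=47.0, distortion_scale=0.0, rotation_scale=0.0
    )


@pytest.fixture(scope="session")
def scene(realistic_rig):
    return tm.make_scene(tm.SceneSpec(seed=5), rig=realistic_rig)


@pytest.fixture(scope="session")
def noiseless_scene(realistic_rig):
    return tm.make_scene(tm.SceneSpec(seed=5, noise_sigma_c=0.0), rig=realistic_rig)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
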