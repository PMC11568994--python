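import numpy as np
import pytest

from conked.synthetic import generate_scene


@pytest.fixture(scope="session")
def scene_small():
    """A deterministic 256x256 scene with a moderate number of keypoints."""
    return generate_scene(seed=7, size=256, n_trees=2, n_branch_events=5)


@pytest.fixture(scope="session")
def scene_dense():
    """A denser scene (more trees and branch events -> more keypoints)."""
    return generate_scene(seed=11, size=256, n_trees=3, n_branch_events=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
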