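import numpy as np
import pytest

from posekit.skeleton import KeypointSet, Skeleton, parse_skeleton
from posekit.synthetic import make_dataset, toy_creature

SIMPLE_SKELETON_CSV = """\
name,parent,swap
body,,
head,body,
tail,body,
left_arm,body,right_arm
right_arm,body,left_arm
"""


@pytest.fixture(scope="session")
def simple_skeleton() -> Skeleton:
    return parse_skeleton(SIMPLE_SKELETON_CSV)


@pytest.fixture(scope="session")
def toy_spec():
    return toy_creature(64, jitter=6.0, noise_level=0.02)


@pytest.fixture(scope="session")
def toy_dataset(toy_spec):
    return make_dataset(toy_spec, 8, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_interior_keypoints(rng, n, shape, margin):
    h, w = shape
    coords = np.column_stack(
        [rng.uniform(margin, w - 1 - margin, n), rng.uniform(margin, h - 1 - margin, n)]
    )
    return KeypointSet(coords)
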