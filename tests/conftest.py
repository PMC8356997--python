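import logging

import numpy as np
import pytest

from lesionorm.lesion_sim import PhantomSpec, make_phantom, make_synthetic_deformation
from lesionorm.registration import RegistrationConfig
from lesionorm.volumes import Geometry, resample

logging.getLogger("lesionorm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom64():
    """Small labeled phantom for fast unit tests."""
    return make_phantom(PhantomSpec(shape=(64, 64), seed=3))


@pytest.fixture(scope="session")
def phantom128():
    """Full-size labeled phantom (the package's default study grid)."""
    return make_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def warped_pair_128(phantom128):
    """Phantom plus its known-warp copy (the recovery ground truth)."""
    img, lab = phantom128
    gt = make_synthetic_deformation(img.geometry, amplitude=4, smoothness=8, seed=5)
    moving = resample(img, gt, interpolation="linear")
    moving_labels = resample(lab, gt, interpolation="nearest")
    return img, lab, gt, moving, moving_labels


@pytest.fixture(scope="session")
def fast_config():
    """Light solver schedule for unit tests on 64^2 grids."""
    return RegistrationConfig(levels=((4, 20), (2, 12), (1, 8)), outer_iterations=1)


def mean_label_jaccard(a, b):
    from lesionorm.evaluation import jaccard

    ids = sorted(a.label_ids | b.label_ids)
    return float(np.mean([jaccard(a.data == l, b.data == l) for l in ids]))
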