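"""Shared fixtures.

The expensive fixture is ``toy_seg_net``: a small flow-field segmentation
network trained once per session on synthetic cytoplasm-style images and
reused by the calibration, perceptual-loss and end-to-end tests.  Its
training conditions are the desk-scale study conditions defined in
``cellrestore.experiments`` (64x64 images, 16 training images, ~18 px
objects, fixed seed).
"""

import pytest

from cellrestore.experiments import DESK, desk_train_config
from cellrestore.simcells import generate_dataset
from cellrestore.train import train_segmentation


@pytest.fixture(scope="session")
def train_images():
    return generate_dataset(16, seed=0, **DESK)


@pytest.fixture(scope="session")
def test_images():
    return generate_dataset(20, seed=1000, **DESK)


@pytest.fixture(scope="session")
def toy_seg_net(train_images):
    net, log = train_segmentation(train_images, desk_train_config(seed=0))
    assert log[-1]["loss"] < log[0]["loss"]
    return net.freeze()
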