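"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dcshape import classify as clf
from dcshape import synthgen as sg
from dcshape.events import EventClass


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_disk_mask(radius: int, pad: int = 8) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


@pytest.fixture(scope="session")
def tiny_classifier():
    """A quickly trained tiny-backbone classifier for inference tests."""
    images, labels = sg.generate_labeled_arrays(
        {c: 60 for c in EventClass}, seed=123)
    cfg = clf.TrainConfig(input_size=32, epochs=3, batch_size=32,
                          learning_rate=3e-4, backbone="tiny", seed=123)
    train_set, val_set = clf.stratified_split(images, labels,
                                              cfg.val_fraction, cfg.seed)
    model = clf.build_model(cfg)
    trained = clf.train(model, train_set, val_set, cfg)
    return trained, val_set
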