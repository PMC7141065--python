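from __future__ import annotations

import numpy as np
import pytest

from scanpathkit import (
    Fixation,
    blend_toward_uniform,
    default_ecg_layout,
    default_model,
)


@pytest.fixture(scope="session")
def ecg_layout():
    return default_ecg_layout()


@pytest.fixture(scope="session")
def correct_model(ecg_layout):
    return default_model(ecg_layout)


@pytest.fixture(scope="session")
def incorrect_model(correct_model):
    return blend_toward_uniform(correct_model, 0.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def make_fixation(pid="P01", sid="ecg", onset=0.0, x=10.0, y=10.0, duration=100.0):
    return Fixation(pid, sid, onset, x, y, duration)


@pytest.fixture()
def fixation_factory():
    return make_fixation


@pytest.fixture()
def fixation_sequence():
    """A strictly onset-ordered fixation list builder from (x, y) points."""

    def build(points, pid="P01", sid="ecg", duration=100.0):
        return [
            Fixation(pid, sid, i * (duration + 30.0), float(x), float(y), duration)
            for i, (x, y) in enumerate(points)
        ]

    return build
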