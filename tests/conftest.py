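"""Shared fixtures: phantoms are expensive, so they are session-scoped and the
full metric derivation runs once."""

from __future__ import annotations

import numpy as np
import pytest

from herniaquant.metrics import derive_all
from herniaquant.surfaces import contours_from_labels, interpolate_walls
from herniaquant.synthetic_data import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default hernia phantom (2 x 2 x 5 mm grid) with ground truth."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def hernia_free_phantom():
    return make_phantom(PhantomSpec(hernia=False))


@pytest.fixture(scope="session")
def fine_phantom():
    """1 x 1 mm in-plane phantom for quantization-sensitive reliability checks."""
    return make_phantom(PhantomSpec(shape=(360, 320, 80), spacing=(1.0, 1.0, 5.0)))


@pytest.fixture(scope="session")
def default_surfaces(default_phantom):
    vol, _ = default_phantom
    return interpolate_walls(contours_from_labels(vol))


@pytest.fixture(scope="session")
def hernia_free_surfaces(hernia_free_phantom):
    vol, _ = hernia_free_phantom
    return interpolate_walls(contours_from_labels(vol))


@pytest.fixture(scope="session")
def default_metrics(default_phantom):
    vol, _ = default_phantom
    return derive_all(vol, subject_id="default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
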