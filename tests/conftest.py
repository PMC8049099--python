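"""Shared fixtures: small axes/bases for fast unit tests."""

import numpy as np
import pytest

from mrsep.axes import SpectralAxis
from mrsep.basis import build_default_basis
from mrsep.params import default_distributions


@pytest.fixture(scope="session")
def axis():
    """Short axis (T=128) keeping unit tests fast; full bandwidth."""
    return SpectralAxis(n_points=128, bandwidth=2000.0)


@pytest.fixture(scope="session")
def full_axis():
    """The acquisition-size axis (T=512, BW 2000 Hz)."""
    return SpectralAxis(n_points=512, bandwidth=2000.0)


@pytest.fixture(scope="session")
def basis(axis):
    return build_default_basis(axis)


@pytest.fixture(scope="session")
def full_basis(full_axis):
    return build_default_basis(full_axis)


@pytest.fixture(scope="session")
def dists():
    return default_distributions()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
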