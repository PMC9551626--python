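"""Shared fixtures: small synthetic acquisitions reused across test modules."""

import numpy as np
import pytest

import dhmkit as dk


@pytest.fixture(scope="session")
def blob_phantom():
    """Smooth cell-like phase object (six Gaussian bumps, peak 1.5 rad)."""
    return dk.make_phantom("blobs", (256, 256), peak_phase=1.5, seed=3)


@pytest.fixture(scope="session")
def offaxis_cfg():
    """Off-axis telecentric acquisition with an on-grid carrier."""
    return dk.AcquisitionConfig.from_carrier_bins(60, 50)


@pytest.fixture(scope="session")
def offaxis_hologram(blob_phantom, offaxis_cfg):
    return dk.simulate_hologram(blob_phantom, offaxis_cfg)


@pytest.fixture(scope="session")
def slight_cfg():
    """Slightly off-axis telecentric acquisition (small carrier)."""
    return dk.AcquisitionConfig.from_carrier_bins(20, 16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def background_mask(phantom):
    return phantom.phase < 1e-3


def wrapped_spread(diff):
    """Spread of a wrapped phase difference map (max deviation from its
    circular mean), robust to the 2*pi branch."""
    z = np.exp(1j * diff)
    mean = np.angle(z.sum())
    return np.abs(np.angle(z * np.exp(-1j * mean))).max()
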