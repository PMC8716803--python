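import numpy as np
import pytest

import o17relax as o


@pytest.fixture(scope="session")
def tse_protocol():
    """The 8-echo, 20-ms-interval turbo-spin-echo timing (TEs 20–160 ms)."""
    return o.tse_t2_protocol()


@pytest.fixture(scope="session")
def layout_pair():
    return o.default_layout_pair()


@pytest.fixture(scope="session")
def phantom_truth(layout_pair, tse_protocol):
    return o.phantom_ground_truth(layout_pair[0], tse_protocol)


@pytest.fixture(scope="session")
def noisy_phantom_series(phantom_truth, tse_protocol):
    """One SNR-50 Rician repeat of the first phantom layout."""
    sigma = o.sigma_for_first_echo_snr(phantom_truth, tse_protocol, snr=50.0)
    noise = o.NoiseModel(kind="rician", sigma=sigma, seed=7)
    return o.simulate_multiecho_series(phantom_truth, tse_protocol, noise)


def uniform_truth(t2_ms, shape=(4, 4, 1), amplitude=1000.0, t1_ms=3000.0):
    """A homogeneous object filling the whole grid (helper for voxel tests)."""
    t2 = np.full(shape, float(t2_ms))
    return o.GroundTruthMaps(
        true_t1=np.full(shape, float(t1_ms)),
        true_t2=t2,
        true_t2star=0.8 * t2,
        true_amplitude=np.full(shape, float(amplitude)),
        concentration_map=np.zeros(shape),
    )
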