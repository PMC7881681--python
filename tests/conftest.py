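import numpy as np
import pytest

from mollifit import (
    RelaxationParams,
    TISeries,
    generate_molli_tis,
    relaxation_signal,
)

PRE_TIS = generate_molli_tis("5(3)3", 1000.0, (120.0, 200.0))
POST_TIS = generate_molli_tis("4(1)3(1)2", 1000.0, (120.0, 200.0, 280.0))


def make_series(params: RelaxationParams, tis=None, magnitude=False,
                noise_sigma=0.0, rng=None) -> TISeries:
    """Forward-simulate one series from known parameters."""
    if tis is None:
        tis = PRE_TIS
    clean = relaxation_signal(params, tis)
    if noise_sigma > 0:
        assert rng is not None
        signal = np.hypot(clean + rng.normal(0, noise_sigma, clean.shape),
                          rng.normal(0, noise_sigma, clean.shape))
        if not magnitude:
            signal = np.sign(clean) * signal  # signed data with matched noise level
    else:
        signal = np.abs(clean) if magnitude else clean
    return TISeries(tis, signal, is_magnitude=magnitude)


@pytest.fixture
def pre_tis():
    return PRE_TIS


@pytest.fixture
def post_tis():
    return POST_TIS


@pytest.fixture
def ideal_params():
    """Ideal inversion (a = -2c): corrected T1 equals apparent T1 = 800 ms."""
    return RelaxationParams(a=300.0, b=1.0 / 800.0, c=-150.0)


@pytest.fixture
def canonical_init_params():
    """The canonical pre-contrast LM starting point (T1 = 750 ms after correction)."""
    return RelaxationParams(a=350.0, b=0.001, c=-150.0)
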