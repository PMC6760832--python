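import numpy as np
import pytest

import chemocal as cc


@pytest.fixture(scope="session")
def train_design():
    return cc.build_calibration_design()


@pytest.fixture(scope="session")
def test_design():
    return cc.build_test_design()


@pytest.fixture(scope="session")
def noiseless_train(train_design):
    """16 training mixture spectra, Beer–Lambert exact (sigma = 0)."""
    return cc.generate_mixture_spectra(train_design, noise=cc.NoiseModel(0.0, 0))


@pytest.fixture(scope="session")
def noiseless_test(test_design):
    return cc.generate_mixture_spectra(test_design, noise=cc.NoiseModel(0.0, 1))


@pytest.fixture(scope="session")
def noisy_train(train_design):
    """Training spectra at the default 0.002 AU noise floor."""
    return cc.generate_mixture_spectra(train_design, noise=cc.NoiseModel(0.002, 42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
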