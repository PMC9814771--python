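import numpy as np
import pytest

from irtomo.chemistry import default_latent_spaces
from irtomo.grids import common_grid
from irtomo.specsim import InstrumentModel, generate_dataset


@pytest.fixture(scope="session")
def nu():
    return common_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def latent_spaces():
    """A small bank of latent chemistry spaces shared across tests."""
    return default_latent_spaces(n_spaces=6, spectra_per_space=24, seed=7)


@pytest.fixture(scope="session")
def clean_instrument():
    """Instrument with every stochastic augmentation switched off."""
    return InstrumentModel(theta_na_jitter=0.0, smoothing_fwhm=0.0,
                           noise_sd=0.0, co2_amplitude=0.0,
                           baseline_sd=(0.0, 0.0, 0.0),
                           radius_perturb_sd=0.0, diffuse_imag=0.0)


@pytest.fixture(scope="session")
def tiny_dataset(latent_spaces):
    """32 augmented records used by several training tests."""
    return generate_dataset(32, seed=42, latent_spaces=latent_spaces)


@pytest.fixture(scope="session")
def clean_dataset(latent_spaces, clean_instrument):
    """16 unaugmented, jitter-free records (deterministic physics only)."""
    return generate_dataset(16, seed=43, latent_spaces=latent_spaces,
                            instrument=clean_instrument, augmented=False)
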