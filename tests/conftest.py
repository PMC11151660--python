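import numpy as np
import pytest

from paox import (LstmHyperparams, default_table, generate_dataset, variant,
                  analytic_config, zscore)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def grid(table):
    return table.grid


@pytest.fixture(scope="session")
def base_small():
    """2000 BASE-variant spectra, raw amplitudes."""
    return generate_dataset(variant("BASE", n_spectra=2000, seed=11))


@pytest.fixture(scope="session")
def base_small_z(base_small):
    return zscore(base_small)


@pytest.fixture(scope="session")
def analytic_ds():
    """Noiseless, attenuation-free spectra: exactly blood-absorption shaped."""
    return generate_dataset(analytic_config(n_spectra=200, seed=5))


def tiny_hyper(**kw):
    """Reduced-width hyperparameters for fast qualitative training runs."""
    defaults = dict(lstm_hidden=24, fc_hidden=64, epochs=12, batch_size=512, seed=0)
    defaults.update(kw)
    return LstmHyperparams(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
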