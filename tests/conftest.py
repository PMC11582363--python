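import numpy as np
import pytest

from roughstage.fixtures import fixture
from roughstage.lstm import LSTMConfig
from roughstage.synth import generate_synthetic
from roughstage.weibull import SurvivalRecord


@pytest.fixture(scope="session")
def table1():
    return fixture("table1")


@pytest.fixture(scope="session")
def table3():
    return fixture("table3")


@pytest.fixture(scope="session")
def table11():
    return fixture("table11")


@pytest.fixture(scope="session")
def strong_signal_system():
    """500 patients with a strong stage signal in the gene columns."""
    return generate_synthetic(500, n_genes=17, effect_size=0.8, seed=11)


@pytest.fixture
def fast_lstm_config():
    """Scaled-down training configuration for unit tests."""
    return LSTMConfig(
        direction="bi", units=12, hidden_layers=1, epochs=20, batch_size=32,
        learning_rate=0.02, dropout=0.1, optimizer="nadam", seed=0,
    )


def make_weibull_records(
    n, shape, scale, censor_mean=None, seed=0, stage=None
):
    """Weibull(shape, scale) records with optional independent exponential
    censoring (censor_mean = mean of the censoring distribution)."""
    rng = np.random.default_rng(seed)
    t_event = scale * rng.weibull(shape, n)
    if censor_mean is None:
        t, d = t_event, np.ones(n, bool)
    else:
        c = rng.exponential(censor_mean, n)
        t = np.minimum(t_event, c)
        d = t_event <= c
    return [
        SurvivalRecord(f"o{i}", float(max(t[i], 1e-9)), int(d[i]), stage)
        for i in range(n)
    ]
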