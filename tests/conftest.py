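import numpy as np
import pandas as pd
import pytest

from springtrigger import DailySeries, SampleSeries, SyntheticParams, generate_study


@pytest.fixture(scope="session")
def coupled_study():
    """One default coupled 7-year study with its ground truth."""
    return generate_study(SyntheticParams(seed=42))


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free coupled conditions: STT equals the injected magnitude and
    the latent peak maps exactly onto the observed one (daily tows)."""
    return SyntheticParams(
        seed=7,
        sst_amplitude=0.0,
        ar_sd=0.0,
        peak_noise_sd=0.0,
        tow_noise_cv=0.0,
        sampling_gap_range=(1, 1),
    )


@pytest.fixture(scope="session")
def quiet_study(quiet_params):
    return generate_study(quiet_params)


@pytest.fixture
def daily_series():
    def make(values, start="2016-01-01", label=""):
        dates = pd.date_range(start, periods=len(values), freq="D")
        return DailySeries.from_pairs(dates, np.asarray(values, float), label)

    return make


@pytest.fixture
def sample_series():
    def make(dates, values):
        return SampleSeries.from_pairs(pd.to_datetime(dates), np.asarray(values, float))

    return make
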