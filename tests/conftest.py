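import numpy as np
import pandas as pd
import pytest

from whalesong.synthetic import NoiseModel, SongScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_noise():
    """Noise model without day-to-day drift, for sharp expectations."""
    return NoiseModel(base_psd_db=95.0, daily_ar1_coeff=0.0,
                      daily_sd_db=0.0, frame_sd_db=0.5)


@pytest.fixture
def always_singing():
    """Song every day of the year, all day long at a 6 dB injection."""
    return SongScenario(species="blue", season_start_doy=1, season_end_doy=366,
                        daily_presence_prob=1.0, call_energy_db=6.0,
                        day_song_fraction=0.5)


@pytest.fixture
def week():
    return pd.date_range("2021-08-01", periods=7, freq="D")
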