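import logging

import numpy as np
import pandas as pd
import pytest

from ecogonset import synth
from ecogonset.data import BandPower, BandSpec, make_channel_table

logging.getLogger("ecogonset").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Fast synthetic recording: 4 channels, 2 fingers x 5 trials."""
    return synth.SynthConfig(
        n_channels=4,
        fs=400.0,
        n_trials_per_finger=5,
        fingers=("thumb", "index"),
        region_of_channel=("M1", "M1", "S1", "S1"),
        true_onset_s=(-0.1, -0.1, 0.0, 0.0),
        seed=7,
    )


@pytest.fixture
def small_recording(small_cfg):
    return synth.generate_recording(small_cfg)


def make_band_power(
    data: np.ndarray,
    fs: float = 100.0,
    band: BandSpec | None = None,
    t0: float = -1.0,
    regions=None,
    fingers=None,
) -> BandPower:
    """Wrap a (trials, channels, times) array as BandPower on a [-1, 2]-style axis."""
    n_trials, n_ch, n_t = data.shape
    band = band or BandSpec("hfb", 60, 100, "increase")
    time_s = t0 + np.arange(n_t) / fs
    channels = make_channel_table(regions or ["M1"] * n_ch)
    fingers = np.asarray(fingers if fingers is not None else ["thumb"] * n_trials)
    return BandPower(data, time_s, fs, fingers, channels, band=band)
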