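"""Morlet time-frequency decomposition and band-power averaging.

The wavelet at frequency ``f`` is a complex exponential under a Gaussian
envelope with temporal SD ``width / (2*pi*f)`` (``width`` = number of
cycles), truncated at ``gwidth`` SDs on each side.  The envelope is
normalized so that a unit-amplitude sinusoid at ``f`` yields power 1.
Samples closer to an epoch edge than the wavelet half-length are
invalidated (NaN) and excluded from all downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .data import BandPower, BandSpec, TrialSet

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 7.0
DEFAULT_GWIDTH = 3.0


def morlet_wavelet(freq: float, fs: float, width: float = DEFAULT_WIDTH,
                   gwidth: float = DEFAULT_GWIDTH) -> np.ndarray:
    """Complex Morlet wavelet; amplitude-normalized (unit sinusoid -> power 1)."""
    if freq <= 0:
        raise ValueError("frequency must be positive")
    sd_t = width / (2.0 * np.pi * freq)
    half = int(np.floor(gwidth * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sd_t**2))
    gauss *= 2.0 / gauss.sum()
    return gauss * np.exp(2j * np.pi * freq * t)


@dataclass
class TimeFrequencyPower:
    """Power (trials x channels x freqs x times); edge samples are NaN."""

    data: np.ndarray
    freqs: np.ndarray
    time_s: np.ndarray
    fs: float
    fingers: np.ndarray
    channels: "object"
    trial_ids: np.ndarray


def _check_freqs(freqs: np.ndarray, fs: float) -> None:
    if freqs.max() >= fs / 2.0:
        raise ValueError(f"frequency {freqs.max()} Hz is at or above Nyquist ({fs / 2} Hz)")
    if freqs.min() <= 0:
        raise ValueError("frequencies must be positive")


def _convolve_power(
    data_f: np.ndarray, wavelet: np.ndarray, nfft: int, n_times: int
) -> np.ndarray:
    """|conv(data, wavelet)|^2 with 'same' alignment, edges set to NaN."""
    wf = fft(wavelet, nfft)
    conv = ifft(data_f * wf, axis=-1)
    start = (wavelet.size - 1) // 2
    power = np.abs(conv[..., start : start + n_times]) ** 2
    half = wavelet.size // 2
    if half > 0:
        power[..., :half] = np.nan
        power[..., -half:] = np.nan
    return power


def morlet_power(
    ts: TrialSet,
    freqs,
    width: float = DEFAULT_WIDTH,
    gwidth: float = DEFAULT_GWIDTH,
    single_precision: bool = False,
) -> TimeFrequencyPower:
    """Per-frequency Morlet power for every trial, channel and sample."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    _check_freqs(freqs, ts.fs)
    n_times = ts.data.shape[2]
    wavelets = [morlet_wavelet(f, ts.fs, width, gwidth) for f in freqs]
    max_len = max(w.size for w in wavelets)
    if max_len > n_times:
        raise ValueError("epoch too short for the lowest-frequency wavelet")
    nfft = next_fast_len(n_times + max_len - 1)
    dtype = np.complex64 if single_precision else np.complex128
    real_dtype = np.float32 if single_precision else np.float64
    data_f = fft(ts.data.astype(real_dtype, copy=False), nfft, axis=-1).astype(dtype)
    out = np.empty(ts.data.shape[:2] + (freqs.size, n_times), dtype=real_dtype)
    for i, w in enumerate(wavelets):
        out[:, :, i, :] = _convolve_power(data_f, w.astype(dtype), nfft, n_times)
    return TimeFrequencyPower(out, freqs, ts.time_s, ts.fs, ts.fingers, ts.channels, ts.trial_ids)


def band_average(tf: TimeFrequencyPower, band: BandSpec) -> BandPower:
    """Arithmetic mean over the band's frequency bins (endpoints included).

    NaN edge samples propagate: a sample is invalid for the band when any
    contributing bin is invalid, so baselines never silently mix in edge
    artifacts.
    """
    sel = (tf.freqs >= band.low) & (tf.freqs <= band.high)
    if not sel.any():
        raise ValueError(f"no computed frequency bins inside band {band.name} "
                         f"[{band.low}, {band.high}] Hz")
    data = tf.data[:, :, sel, :].mean(axis=2)
    return BandPower(data, tf.time_s, tf.fs, tf.fingers, tf.channels, tf.trial_ids, band=band)


def compute_band_power(
    ts: TrialSet,
    band: BandSpec,
    freq_step: float = 1.0,
    width: float = DEFAULT_WIDTH,
    gwidth: float = DEFAULT_GWIDTH,
    single_precision: bool = False,
) -> BandPower:
    """Band-averaged Morlet power at ``freq_step`` Hz bins, fused to avoid
    materializing the full time-frequency array."""
    freqs = np.arange(band.low, band.high + freq_step / 2.0, freq_step)
    _check_freqs(freqs, ts.fs)
    n_times = ts.data.shape[2]
    wavelets = [morlet_wavelet(f, ts.fs, width, gwidth) for f in freqs]
    max_len = max(w.size for w in wavelets)
    if max_len > n_times:
        raise ValueError("epoch too short for the lowest-frequency wavelet")
    nfft = next_fast_len(n_times + max_len - 1)
    dtype = np.complex64 if single_precision else np.complex128
    real_dtype = np.float32 if single_precision else np.float64
    data_f = fft(ts.data.astype(real_dtype, copy=False), nfft, axis=-1).astype(dtype)
    acc = np.zeros(ts.data.shape[:2] + (n_times,), dtype=real_dtype)
    for w in wavelets:
        acc += _convolve_power(data_f, w.astype(dtype), nfft, n_times)
    acc /= len(wavelets)
    return BandPower(acc, ts.time_s, ts.fs, ts.fingers, ts.channels, ts.trial_ids, band=band)
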