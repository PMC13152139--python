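"""Synthetic multichannel ECoG-like data with known ground truth.

The generator produces the statistical structure the downstream analysis
assumes: a 1/f background, optional line noise, a continuous low-frequency
rhythm (8-30 Hz) whose amplitude is suppressed around movement, and a
broadband high-frequency component (60-100 Hz) whose amplitude increases
around movement.  Band-limited components are amplitude-modulated filtered
Gaussian noise, not pure tones, so wavelet band power (not narrowband
phase) carries the injected effect.

Per-channel onset lags are fixed across trials; per-trial reaction-time
jitter shifts all channels of a trial together.  The modulation envelope is
a raised-cosine ramp; the ground-truth onset is the ramp start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .data import GloveTrace, GroundTruth, Recording, make_channel_table, make_event_table

logger = logging.getLogger(__name__)

#: Amplitude-modulation depths below this leave the injected band-power
#: effect statistically unreliable at 30 trials (documented SNR floor).
SNR_FLOOR_GAIN = 0.5


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording.

    ``true_onset_s`` holds per-channel neural-onset lags in seconds
    relative to the true movement onset (negative = before movement).
    """

    n_channels: int = 8
    fs: float = 512.0
    n_trials_per_finger: int = 30
    fingers: tuple[str, ...] = ("thumb", "index", "little")
    region_of_channel: tuple[str, ...] | None = None
    true_onset_s: tuple[float, ...] | None = None
    modulated_channels: tuple[bool, ...] | None = None
    in_hand_region: tuple[bool, ...] | None = None
    hfb_gain: float = 3.0
    lfb_gain: float = 0.8
    reaction_time_s: float = 0.35
    reaction_time_jitter_sd: float = 0.05
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    line_noise_amp: float = 0.0
    bad_channel_ids: tuple[int, ...] = ()
    intertrial_range_s: tuple[float, float] = (4.4, 5.0)
    rise_time_s: float = 0.2
    burst_duration_s: float = 1.0
    burst_duration_per_channel: tuple[float, ...] | None = None
    fall_time_s: float = 0.3
    hfb_carrier_amp: float = 0.6
    lfb_carrier_amp: float = 1.0
    pad_s: float = 3.0
    glove_noise_sd: float = 0.002
    glove_rise_s: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials_per_finger < 1:
            raise ValueError("n_trials_per_finger must be >= 1")
        if self.region_of_channel is None:
            # alternate M1/S1 by default
            self.region_of_channel = tuple(
                "M1" if i < self.n_channels // 2 else "S1" for i in range(self.n_channels)
            )
        if self.true_onset_s is None:
            self.true_onset_s = tuple(np.zeros(self.n_channels))
        if len(self.region_of_channel) != self.n_channels:
            raise ValueError("region_of_channel must have one entry per channel")
        if len(self.true_onset_s) != self.n_channels:
            raise ValueError("true_onset_s must have one entry per channel")
        if self.hfb_gain < 0 or self.lfb_gain < 0:
            raise ValueError("modulation gains must be non-negative")
        if not 0 <= self.lfb_gain <= 1:
            raise ValueError("lfb_gain must lie in [0, 1] (it suppresses amplitude)")
        onsets = np.asarray(self.true_onset_s, dtype=float)
        if np.any(onsets < -1.0) or np.any(onsets > 2.0):
            raise ValueError("true onsets must lie within [-1, 2] s of movement onset")
        lo, hi = self.intertrial_range_s
        if not 0 < lo <= hi:
            raise ValueError("invalid intertrial range")
        if self.burst_duration_per_channel is None:
            self.burst_duration_per_channel = (self.burst_duration_s,) * self.n_channels
        if len(self.burst_duration_per_channel) != self.n_channels:
            raise ValueError("burst_duration_per_channel must have one entry per channel")
        if self.modulated_channels is None:
            self.modulated_channels = (True,) * self.n_channels
        if len(self.modulated_channels) != self.n_channels:
            raise ValueError("modulated_channels must have one entry per channel")
        if self.in_hand_region is None:
            self.in_hand_region = tuple(r in ("M1", "S1") for r in self.region_of_channel)
        if len(self.in_hand_region) != self.n_channels:
            raise ValueError("in_hand_region must have one entry per channel")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_finger * len(self.fingers)


def _powerlaw_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    n_fast = next_fast_len(n)  # awkward lengths make the FFT the bottleneck
    spec = rfft(white, n_fast)
    f = rfftfreq(n_fast)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = irfft(spec * scale, n_fast)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(
    n: int, fs: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-pass filtered white noise with unit variance."""
    sos = sps.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _raised_cosine_window(
    t: np.ndarray, start: float, rise: float, hold: float, fall: float
) -> np.ndarray:
    """0 before ``start``; raised-cosine ramp to 1 over ``rise``; hold; fall."""
    env = np.zeros_like(t)
    u = (t - start) / max(rise, 1e-9)
    rising = (u > 0) & (u < 1)
    env[rising] = 0.5 * (1 - np.cos(np.pi * u[rising]))
    t_hold_end = start + rise + hold
    env[(t >= start + rise) & (t < t_hold_end)] = 1.0
    v = (t - t_hold_end) / max(fall, 1e-9)
    falling = (v >= 0) & (v < 1)
    env[falling] = 0.5 * (1 + np.cos(np.pi * v[falling]))
    return env


def _add_bursts(
    env: np.ndarray, fs: float, starts: np.ndarray, rise: float, hold: float, fall: float
) -> None:
    """Accumulate raised-cosine burst windows in place, touching only the
    active slice of each burst (the full-length evaluation dominates
    generation cost otherwise)."""
    n = env.size
    total = rise + hold + fall
    for start in starts:
        i0 = max(int(np.floor(start * fs)), 0)
        i1 = min(int(np.ceil((start + total) * fs)) + 1, n)
        if i0 >= n or i1 <= 0:
            continue
        t_local = np.arange(i0, i1) / fs
        env[i0:i1] += _raised_cosine_window(t_local, start, rise, hold, fall)


def _trial_schedule(cfg: SynthConfig, rng: np.random.Generator):
    """Randomized finger order, cue times and true movement times."""
    fingers = np.repeat(list(cfg.fingers), cfg.n_trials_per_finger)
    fingers = fingers[rng.permutation(fingers.size)]
    gaps = rng.uniform(*cfg.intertrial_range_s, size=fingers.size)
    cues = cfg.pad_s + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    jitter = rng.normal(0.0, cfg.reaction_time_jitter_sd, size=fingers.size)
    movement = cues + cfg.reaction_time_s + jitter
    return fingers, cues, movement


def generate_recording(cfg: SynthConfig) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Generate a continuous recording, its event table and the ground truth.

    Deterministic for a fixed ``cfg`` (including ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    fingers, cues, movement = _trial_schedule(cfg, rng)

    duration = (
        movement[-1] + cfg.rise_time_s + max(cfg.burst_duration_per_channel)
        + cfg.fall_time_s + cfg.pad_s
    )
    n = int(np.ceil(duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    signal = np.empty((cfg.n_channels, n))
    line = cfg.line_noise_amp * np.sin(2 * np.pi * 50.0 * t) if cfg.line_noise_amp else 0.0

    for ch in range(cfg.n_channels):
        background = cfg.noise_amp * _powerlaw_noise(n, cfg.noise_exponent, rng)
        hfb_carrier = _bandlimited_noise(n, cfg.fs, 60.0, 100.0, rng)
        lfb_carrier = _bandlimited_noise(n, cfg.fs, 8.0, 30.0, rng)
        env = np.zeros(n)
        if cfg.modulated_channels[ch]:
            _add_bursts(
                env, cfg.fs, movement + cfg.true_onset_s[ch],
                cfg.rise_time_s, cfg.burst_duration_per_channel[ch], cfg.fall_time_s,
            )
            np.clip(env, 0.0, 1.0, out=env)
        signal[ch] = (
            background
            + line
            + cfg.hfb_carrier_amp * hfb_carrier * (1.0 + cfg.hfb_gain * env)
            + cfg.lfb_carrier_amp * lfb_carrier * (1.0 - cfg.lfb_gain * env)
        )

    for k, ch in enumerate(cfg.bad_channel_ids):
        if k % 2 == 0:  # alternate flat / high-variance failure modes
            signal[ch] = 0.0
        else:
            signal[ch] = 40.0 * cfg.noise_amp * rng.standard_normal(n)

    channels = make_channel_table(
        list(cfg.region_of_channel), in_hand_region=list(cfg.in_hand_region)
    )
    rec = Recording(signal, cfg.fs, channels)
    events = make_event_table(list(fingers), cues)
    gt = GroundTruth(movement, np.asarray(cfg.true_onset_s), list(cfg.region_of_channel))
    return rec, events, gt


def generate_glove(events: pd.DataFrame, gt: GroundTruth, cfg: SynthConfig) -> GloveTrace:
    """Per-finger dataglove traces with a sigmoidal deflection per trial.

    The deflection of the moved finger's sensor begins exactly at the
    trial's true movement time (zero derivative before, positive just
    after), rises over ``cfg.glove_rise_s``, and relaxes back to baseline.
    """
    if len(events) != gt.true_movement_time_s.size:
        raise ValueError("one movement time per trial required")
    rng = np.random.default_rng(cfg.seed + 104729)  # independent of the ECoG stream
    duration = gt.true_movement_time_s[-1] + 3.0
    n = int(np.ceil(duration * cfg.fs))
    traces = np.zeros((len(cfg.fingers), n))
    finger_idx = {f: i for i, f in enumerate(cfg.fingers)}
    for finger, mv in zip(events["finger"], gt.true_movement_time_s):
        _add_bursts(traces[finger_idx[finger]], cfg.fs, np.array([mv]),
                    cfg.glove_rise_s, 0.5, 0.4)
    if cfg.glove_noise_sd > 0:
        traces += rng.normal(0.0, cfg.glove_noise_sd, size=traces.shape)
    return GloveTrace(traces, list(cfg.fingers), cfg.fs)
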