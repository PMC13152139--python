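"""Bad-channel screening, common-average referencing, filtering, epoching
and trial rejection."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scipy import signal as sps

from .data import Recording, TrialSet

logger = logging.getLogger(__name__)

#: Robust variance-threshold factors relative to the median channel variance.
DEFAULT_VARIANCE_LOW = 1e-3
DEFAULT_VARIANCE_HIGH = 25.0

DEFAULT_EPOCH_WINDOW = (-1.0, 2.0)


def detect_bad_channels(
    rec: Recording,
    variance_low: float = DEFAULT_VARIANCE_LOW,
    variance_high: float = DEFAULT_VARIANCE_HIGH,
    force_bad: tuple[int, ...] = (),
) -> Recording:
    """Flag flat or abnormally noisy channels.

    Thresholds are factors applied to the median channel variance: a channel
    is bad when its variance falls below ``variance_low * median`` (flat,
    e.g. broken lead) or above ``variance_high * median`` (noisy).
    ``force_bad`` is a manual override list of channel indices.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels for bad-channel screening")
    out = rec.copy()
    var = out.signal.var(axis=1)
    med = float(np.median(var))
    bad = (var < variance_low * med) | (var > variance_high * med)
    bad[list(force_bad)] = True
    out.channels["bad"] = bad
    n_bad = int(bad.sum())
    if n_bad == rec.n_channels:
        raise ValueError("all channels flagged bad; check the recording or thresholds")
    if n_bad:
        names = out.channels.loc[bad, "name"].tolist()
        logger.info("flagged %d bad channel(s): %s", n_bad, names)
    return out


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample mean of all good in-CAR channels.

    The reference pool may include channels that are excluded from the
    analysis proper; every retained (non-bad) channel is re-referenced.
    """
    out = rec.copy()
    pool = (out.channels["in_car"] & ~out.channels["bad"]).to_numpy()
    if pool.sum() < 2:
        raise ValueError("common average reference needs >= 2 good in-CAR channels")
    ref = out.signal[pool].mean(axis=0)
    keep = (~out.channels["bad"]).to_numpy()
    out.signal[keep] -= ref
    return out


def equalize_filter(
    rec: Recording,
    band: tuple[float, float] = (0.15, 134.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass plus notch, applied to every channel.

    Forward-backward (zero-phase) filtering is used throughout because onset
    latency is the measurand and phase delay would bias it: 4th-order
    Butterworth band-pass, 2nd-order IIR notch of quality ``notch_q``.
    """
    nyq = rec.fs / 2.0
    if band[1] >= nyq:
        raise ValueError(
            f"band edge {band[1]} Hz is at or above Nyquist ({nyq} Hz); "
            f"sampling rate {rec.fs} Hz is too low"
        )
    out = rec.copy()
    sos = sps.butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    out.signal = sps.sosfiltfilt(sos, out.signal, axis=1)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rec.fs)
        out.signal = sps.filtfilt(b, a, out.signal, axis=1)
    return out


def epoch(
    rec: Recording,
    events: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> TrialSet:
    """Cut one trial per non-excluded event, aligned to its marker.

    Endpoint convention: samples ``round(w0*fs) .. round(w1*fs)`` relative
    to the marker sample, both ends inclusive, so a (-1, 2) window at
    ``fs`` yields ``round(3*fs) + 1`` samples.  Trials whose window falls
    partly outside the recording are dropped with a warning.  Bad channels
    are removed here and never reappear downstream.
    """
    keep_events = events.loc[~events["excluded"]]
    if keep_events["marker_time_s"].isna().any():
        missing = keep_events.loc[keep_events["marker_time_s"].isna(), "trial_id"].tolist()
        raise ValueError(f"events without marker_time_s: trials {missing}")
    lo = int(round(window[0] * rec.fs))
    hi = int(round(window[1] * rec.fs))
    time_s = np.arange(lo, hi + 1) / rec.fs
    good = (~rec.channels["bad"]).to_numpy()
    sig = rec.signal[good]
    chans = rec.channels.loc[good].reset_index(drop=True)

    data, fingers, trial_ids = [], [], []
    n_dropped = 0
    for _, ev in keep_events.iterrows():
        m = int(round(ev["marker_time_s"] * rec.fs))
        a, b = m + lo, m + hi
        if a < 0 or b >= rec.n_samples:
            n_dropped += 1
            continue
        data.append(sig[:, a : b + 1])
        fingers.append(ev["finger"])
        trial_ids.append(ev["trial_id"])
    if n_dropped:
        logger.warning("dropped %d trial(s) with partial windows at recording edges", n_dropped)
    if not data:
        raise ValueError("no trials could be epoched")
    return TrialSet(
        np.stack(data), time_s, rec.fs, np.asarray(fingers), chans, np.asarray(trial_ids)
    )


def reject_trials(
    ts: TrialSet,
    manual_exclusions: tuple[int, ...] = (),
    amplitude_z_limit: float = 10.0,
) -> TrialSet:
    """Drop manually listed trials plus automated amplitude outliers.

    A trial is an amplitude outlier when its peak absolute z-scored
    amplitude (z per channel over all trials and samples) exceeds
    ``amplitude_z_limit`` on any channel.
    """
    manual = np.isin(ts.trial_ids, list(manual_exclusions))
    mu = ts.data.mean(axis=(0, 2), keepdims=True)
    sd = ts.data.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    peak_z = np.abs((ts.data - mu) / sd).max(axis=(1, 2))
    auto = peak_z > amplitude_z_limit
    drop = manual | auto
    if drop.all():
        raise ValueError("all trials rejected")
    if drop.any():
        logger.info(
            "rejected %d trial(s): %d manual, %d amplitude (z > %g)",
            int(drop.sum()), int(manual.sum()), int((auto & ~manual).sum()), amplitude_z_limit,
        )
    return ts.select_trials(~drop)
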