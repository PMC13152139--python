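"""Neural-onset detection with adaptive threshold optimization.

Per channel the trial-averaged, smoothed, z-scored and baseline-corrected
band-power trace is thresholded; the threshold is optimized per
finger/band in two phases on a fixed grid (start magnitude 0.4, step 0.1):

* phase 1 grows the magnitude until it clears the trace value at t = -0.5 s
  of all but ``spare_channels`` channels;
* phase 2 keeps growing while the number of channels reaching the
  threshold inside the optimization window does not drop, and returns the
  last value before the drop.

The permissive variant stops after phase 1.  Onset = first crossing of the
threshold in the band's direction anywhere in the epoch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BandPower, BandSpec

logger = logging.getLogger(__name__)

BASELINE_INTERVAL = (-1.0, -0.5)


def moving_average(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """NaN-aware centered moving average along the last axis.

    The effective kernel is ``2*floor(round(window_s*fs)/2) + 1`` samples
    (rounded to an odd length for exact centering); windows shrink at the
    edges.  NaN samples are excluded from the local mean; positions whose
    window holds no finite sample stay NaN.
    """
    w = int(round(window_s * fs))
    half = max(w // 2, 0)
    if half == 0:
        return x.copy()
    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)
    csum = np.cumsum(filled, axis=-1)
    ccnt = np.cumsum(valid, axis=-1)
    n = x.shape[-1]
    lo = np.clip(np.arange(n) - half, 0, n - 1)
    hi = np.clip(np.arange(n) + half, 0, n - 1)

    def _window_sum(c):
        s = c[..., hi]
        s_lo = np.where(lo > 0, c[..., np.maximum(lo - 1, 0)], 0)
        return s - s_lo

    sums = _window_sum(csum)
    counts = _window_sum(ccnt)
    out = np.full_like(x, np.nan, dtype=float)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def smooth_trials(bp: BandPower, window_s: float = 0.5) -> BandPower:
    """Centered moving-average smoothing of every trial's time course."""
    epoch_len = bp.time_s[-1] - bp.time_s[0]
    if window_s >= epoch_len:
        raise ValueError("smoothing window must be shorter than the epoch")
    data = moving_average(bp.data, window_s, bp.fs)
    return BandPower(data, bp.time_s, bp.fs, bp.fingers, bp.channels, bp.trial_ids, band=bp.band)


@dataclass
class NormalizedTraces:
    """Per-channel z-scored, baseline-corrected trial-mean band power."""

    z: np.ndarray  # (n_channels, n_times)
    time_s: np.ndarray
    fs: float
    band: BandSpec
    channels: pd.DataFrame

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]

    def select_channels(self, idx: np.ndarray) -> "NormalizedTraces":
        idx = np.asarray(idx)
        return NormalizedTraces(
            self.z[idx], self.time_s, self.fs, self.band,
            self.channels.iloc[idx].reset_index(drop=True),
        )


def normalize_channels(
    bp: BandPower, baseline: tuple[float, float] = BASELINE_INTERVAL
) -> NormalizedTraces:
    """Trial mean -> z-score over the full epoch -> baseline mean subtracted.

    Channels with zero variance are dropped with a diagnostic (they cannot
    be z-scored).  After baseline correction the mean of the baseline
    interval is 0 for every channel by construction.
    """
    if bp.n_trials < 1:
        raise ValueError("need at least one trial")
    with warnings.catch_warnings():
        # epoch-edge samples are all-NaN across trials by design
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        m = np.nanmean(bp.data, axis=0)  # (channels, times)
    mu = np.nanmean(m, axis=1, keepdims=True)
    sd = np.nanstd(m, axis=1, keepdims=True)
    # relative guard: rounding dust on a constant trace is still "flat"
    sd_floor = 1e-10 * np.maximum(np.abs(mu[:, 0]), np.finfo(float).tiny)
    flat = (sd[:, 0] <= sd_floor) | ~np.isfinite(sd[:, 0])
    if flat.any():
        names = bp.channels.loc[flat, "name"].tolist()
        logger.warning("dropping zero-variance channel(s) during normalization: %s", names)
    keep = ~flat
    if not keep.any():
        raise ValueError("all channels have zero variance; cannot normalize")
    z = (m[keep] - mu[keep]) / sd[keep]
    sel = (bp.time_s >= baseline[0]) & (bp.time_s <= baseline[1])
    if not sel.any():
        raise ValueError(f"baseline interval {baseline} outside the epoch")
    z = z - np.nanmean(z[:, sel], axis=1, keepdims=True)
    return NormalizedTraces(
        z, bp.time_s, bp.fs, bp.band,
        bp.channels.loc[keep].reset_index(drop=True),
    )


@dataclass
class ThresholdSearch:
    """Grid parameters of the adaptive threshold optimization."""

    start: float = 0.4
    step: float = 0.1
    window: tuple[float, float] = (-0.5, 0.5)
    spare_channels: int = 2
    anchor_time_s: float = -0.5

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.start <= 0:
            raise ValueError("start is a magnitude and must be positive")


def _signed_view(traces: NormalizedTraces) -> np.ndarray:
    """Traces flipped so the band's response direction is always 'up'."""
    return traces.z * traces.band.sign


def _window_maxima(v: np.ndarray, time_s: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    sel = (time_s >= window[0]) & (time_s <= window[1])
    if not sel.any():
        raise ValueError(f"optimization window {window} outside the epoch")
    return np.nanmax(v[:, sel], axis=1)


def optimize_threshold(
    traces: NormalizedTraces,
    search: ThresholdSearch = ThresholdSearch(),
    permissive: bool = False,
) -> float:
    """Optimized threshold in signed z-units (negative for decrease bands).

    With fewer than 3 channels the phase-1 "all but two" condition is
    vacuous; the start magnitude is returned unchanged with a warning.
    If no channel ever reaches the start magnitude inside the window, a
    ``ValueError`` is raised so the caller can skip the band/finger.
    """
    v = _signed_view(traces)
    sign = traces.band.sign
    if traces.n_channels < 3:
        logger.warning(
            "threshold optimization with %d channel(s): falling back to fixed start %.2f",
            traces.n_channels, search.start,
        )
        return sign * search.start

    i_anchor = int(np.argmin(np.abs(traces.time_s - search.anchor_time_s)))
    anchor_vals = v[:, i_anchor]
    maxima = _window_maxima(v, traces.time_s, search.window)
    if not np.any(maxima >= search.start):
        raise ValueError(
            f"no channel reaches magnitude {search.start} inside the window; "
            "skipping this band/finger"
        )
    grid_cap = np.nanmax(maxima) + search.step

    # phase 1: clear the anchor-time value of all but `spare_channels` channels
    thr = search.start
    while np.sum(anchor_vals >= thr) > search.spare_channels and thr <= grid_cap:
        thr += search.step
    if permissive:
        return sign * thr

    # phase 2: grow while the count of channels reaching the threshold
    # inside the window does not drop
    count = int(np.sum(maxima >= thr))
    while True:
        nxt = thr + search.step
        if nxt > grid_cap:
            logger.warning("threshold count never dropped; returning largest reached value")
            return sign * thr
        nxt_count = int(np.sum(maxima >= nxt))
        if nxt_count < count:
            return sign * thr
        thr, count = nxt, nxt_count


def detect_onsets(
    traces: NormalizedTraces,
    threshold: float,
    finger: str = "",
) -> pd.DataFrame:
    """First threshold crossing per channel, over the full epoch.

    Returns one row per crossing channel: ``channel``, ``finger``,
    ``band``, ``onset_s``, ``threshold_used``, ``region`` and
    ``pre_baseline`` (crossing earlier than -0.5 s, reported as-is but
    flagged).  Channels that never cross are omitted with a log entry.
    """
    v = _signed_view(traces)
    thr = abs(threshold)
    rows = []
    for i in range(traces.n_channels):
        above = np.nonzero(np.isfinite(v[i]) & (v[i] >= thr))[0]
        if above.size == 0:
            logger.info(
                "channel %s never crosses threshold %.2f; omitted",
                traces.channels.at[i, "name"], threshold,
            )
            continue
        onset = traces.time_s[above[0]]
        rows.append(
            {
                "channel": traces.channels.at[i, "name"],
                "finger": finger,
                "band": traces.band.name,
                "onset_s": onset,
                "threshold_used": traces.band.sign * thr,
                "region": traces.channels.at[i, "region"],
                "pre_baseline": bool(onset < -0.5),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["channel", "finger", "band", "onset_s", "threshold_used", "region", "pre_baseline"],
    )


def detect_onsets_optimized(
    traces: NormalizedTraces,
    search: ThresholdSearch = ThresholdSearch(),
    finger: str = "",
) -> pd.DataFrame:
    """Full two-phase threshold optimization followed by onset detection."""
    thr = optimize_threshold(traces, search, permissive=False)
    return detect_onsets(traces, thr, finger)


def detect_onsets_permissive(
    traces: NormalizedTraces,
    search: ThresholdSearch = ThresholdSearch(),
    finger: str = "",
) -> pd.DataFrame:
    """Permissive variant: the threshold search stops after phase 1."""
    thr = optimize_threshold(traces, search, permissive=True)
    return detect_onsets(traces, thr, finger)


def mean_threshold(thresholds) -> float:
    """Arithmetic mean of per-participant optimized thresholds (used only
    for the group scatter/histogram display)."""
    arr = np.asarray(list(thresholds), dtype=float)
    if arr.size == 0:
        raise ValueError("no thresholds to average")
    return float(arr.mean())
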