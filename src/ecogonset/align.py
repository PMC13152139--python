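"""Per-trial movement markers.

Two routes: MOM (movement-onset marker) from dataglove traces for executed
movement, and GSM (gamma-slope marker) from the mean high-frequency
band-power response for attempted movement without an overt trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import BandPower, GloveTrace
from .onset import moving_average

logger = logging.getLogger(__name__)


@dataclass
class GsmConfig:
    """Parameters of gamma-slope-marker alignment.

    ``pre_interval_s`` / ``post_interval_s`` are the cue-relative intervals
    used to select task-responsive channels; the slope segment is a line of
    ``slope`` z-units/s and length ``segment_len_s`` slid across
    ``search_window_s``.
    """

    band: tuple[float, float] = (60.0, 100.0)
    pre_interval_s: tuple[float, float] = (-0.5, 0.0)
    post_interval_s: tuple[float, float] = (0.5, 1.0)
    slope: float = 2.0
    segment_len_s: float = 0.4
    search_window_s: tuple[float, float] = (0.0, 2.0)
    smooth_window_s: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.pre_interval_s[1] > 0:
            raise ValueError("pre interval must end at or before the cue")
        if self.post_interval_s[0] < 0:
            raise ValueError("post interval must start at or after the cue")


def _gaussian_derivative_kernel(sigma_s: float, fs: float) -> np.ndarray:
    half = max(int(round(3 * sigma_s * fs)), 1)
    t = np.arange(-half, half + 1) / fs
    g = np.exp(-(t**2) / (2 * sigma_s**2))
    dg = -t / sigma_s**2 * g
    # normalize so a unit-slope ramp maps to unit response
    resp = float(np.sum(dg * -t))
    return dg / resp


def detect_mom(
    glove: GloveTrace,
    events: pd.DataFrame,
    sigma_s: float = 0.05,
    deflect_z: float = 3.0,
    overrides: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Movement-onset markers from the dataglove.

    Per trial the moved finger's trace is convolved with a
    derivative-of-Gaussian kernel (scale ``sigma_s``); the marker is the
    first time after the cue where the convolved signal exceeds
    ``deflect_z`` baseline SDs (baseline = the 0.5 s before the cue).
    Trials with no crossing before the next cue are flagged excluded.
    ``overrides`` maps trial_id -> manually corrected marker time.
    """
    out = events.copy()
    kernel = _gaussian_derivative_kernel(sigma_s, glove.fs)
    n = glove.traces.shape[1]
    convolved = {
        f: np.convolve(glove.trace_for(f), kernel, mode="same") for f in glove.fingers
    }
    cues = out["cue_time_s"].to_numpy()
    next_cue = np.append(cues[1:], n / glove.fs)
    overrides = overrides or {}
    markers = np.full(len(out), np.nan)
    excluded = out["excluded"].to_numpy().copy()
    # floor for noise-free traces: a baseline SD of ~0 would let any
    # numerical ripple cross the deflection threshold at the cue; the floor
    # defines "deflection" as ~1% of the peak convolved response
    sd_floor = {f: 1e-2 * np.abs(c).max() for f, c in convolved.items()}
    for i, (_, ev) in enumerate(out.iterrows()):
        if ev["trial_id"] in overrides:
            markers[i] = overrides[ev["trial_id"]]
            continue
        c = convolved[ev["finger"]]
        i_cue = int(round(ev["cue_time_s"] * glove.fs))
        i_base = max(i_cue - int(round(0.5 * glove.fs)), 0)
        base = c[i_base:i_cue]
        mu, sd = (base.mean(), base.std()) if base.size else (0.0, 0.0)
        sd = max(sd, sd_floor[ev["finger"]], 1e-12)
        i_end = min(int(round(next_cue[i] * glove.fs)), n)
        seg = c[i_cue:i_end]
        above = np.nonzero(seg > mu + deflect_z * sd)[0]
        if above.size == 0:
            excluded[i] = True
            logger.warning("trial %s: no glove deflection found; excluded", ev["trial_id"])
            continue
        markers[i] = (i_cue + above[0]) / glove.fs
    out["marker_time_s"] = markers
    out["excluded"] = excluded
    return out


def _interval_means(bp: BandPower, interval: tuple[float, float]) -> np.ndarray:
    sel = (bp.time_s >= interval[0]) & (bp.time_s <= interval[1])
    if not sel.any():
        raise ValueError(f"interval {interval} outside the epoch")
    return np.nanmean(bp.data[:, :, sel], axis=2)  # (trials, channels)


def select_responsive_channels_for_gsm(cue_bp: BandPower, cfg: GsmConfig) -> np.ndarray:
    """Indices of channels whose post-cue HFB power exceeds pre-cue power.

    Two-sample (independent) one-sided t-test on per-trial interval means,
    p < ``cfg.alpha``.
    """
    pre = _interval_means(cue_bp, cfg.pre_interval_s)
    post = _interval_means(cue_bp, cfg.post_interval_s)
    res = stats.ttest_ind(post, pre, axis=0, alternative="greater")
    sel = np.nonzero(res.pvalue < cfg.alpha)[0]
    if sel.size == 0:
        raise ValueError("GSM aborted: no channel shows a significant HFB response")
    return sel


def _segment_midlevel_crossing(
    trace: np.ndarray, time_s: np.ndarray, cfg: GsmConfig
) -> np.ndarray:
    """Horizontal distance between the trace and the sliding slope segment.

    The segment rises from 0 to ``slope * segment_len_s`` z-units; its
    mid-level is ``slope * segment_len_s / 2``.  For a candidate placement
    (segment midpoint time) the distance is the absolute time difference
    between the midpoint and the trace's first upward crossing of the
    mid-level.  Returns the distance per candidate sample (NaN where the
    trace never crosses).  Isolated here so the metric can be substituted.
    """
    mid_level = cfg.slope * cfg.segment_len_s / 2.0
    in_win = (time_s >= cfg.search_window_s[0]) & (time_s <= cfg.search_window_s[1])
    dist = np.full(time_s.size, np.nan)
    valid = np.isfinite(trace)
    crossing = np.nonzero(in_win & valid & (trace >= mid_level))[0]
    if crossing.size == 0:
        return dist
    t_cross = time_s[crossing[0]]
    dist[in_win] = np.abs(time_s[in_win] - t_cross)
    return dist


def detect_gsm(
    cue_bp: BandPower,
    channels: np.ndarray,
    cfg: GsmConfig,
    events: pd.DataFrame,
) -> pd.DataFrame:
    """Gamma-slope markers: per-trial alignment from the mean HFB response.

    Per trial the band power is averaged over the selected channels,
    smoothed, z-scored, and matched against the sliding slope segment; the
    marker is the placement minimizing the horizontal distance.  Because
    every channel of a trial is shifted by the same amount, relative
    inter-channel timing is preserved.  Trials without a minimum inside the
    search window are flagged excluded ("did not converge"); if more than
    half the trials fail the method aborts.

    Returned marker times are absolute (cue time + within-epoch offset).
    """
    if channels.size == 0:
        raise ValueError("no channels selected for GSM")
    with warnings.catch_warnings():
        # epoch-edge samples are all-NaN by design
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        mean_trace = np.nanmean(cue_bp.data[:, channels, :], axis=1)  # (trials, times)
    mean_trace = moving_average(mean_trace, cfg.smooth_window_s, cue_bp.fs)
    out = events.copy()
    markers = out["marker_time_s"].to_numpy(dtype=float).copy()
    excluded = out["excluded"].to_numpy().copy()
    id_to_row = {tid: i for i, tid in enumerate(out["trial_id"])}
    n_fail = 0
    for k, tid in enumerate(cue_bp.trial_ids):
        trace = mean_trace[k]
        mu = np.nanmean(trace)
        sd = np.nanstd(trace)
        z = (trace - mu) / sd if sd > 0 else trace - mu
        dist = _segment_midlevel_crossing(z, cue_bp.time_s, cfg)
        row = id_to_row[tid]
        if not np.isfinite(dist).any():
            excluded[row] = True
            n_fail += 1
            continue
        offset = cue_bp.time_s[np.nanargmin(dist)]
        markers[row] = out.at[row, "cue_time_s"] + offset
    if n_fail > cue_bp.n_trials / 2:
        raise ValueError(f"GSM did not converge on {n_fail}/{cue_bp.n_trials} trials")
    if n_fail:
        logger.warning("GSM did not converge on %d trial(s); excluded", n_fail)
    out["marker_time_s"] = markers
    out["excluded"] = excluded
    return out
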