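"""End-to-end orchestration helpers for synthetic-cohort runs.

These wire the stage modules together in the canonical order: synthesis ->
bad-channel screening -> CAR -> equalizing filters -> glove-based marker
detection -> epoching -> trial rejection -> band power -> responsive-channel
selection -> smoothing -> normalization -> threshold-optimized onset
detection.  Used by the command line, the acceptance checks and the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align, onset, preprocess, select, spectral, synth
from .data import DEFAULT_BANDS, BandSpec

logger = logging.getLogger(__name__)


@dataclass
class ParticipantResult:
    """Onset tables and bookkeeping for one synthetic participant."""

    onsets: pd.DataFrame                  # full (two-phase) thresholding
    onsets_permissive: pd.DataFrame       # phase-1-only thresholding
    thresholds: dict[str, float] = field(default_factory=dict)
    ground_truth: "object" = None
    n_trials_used: int = 0


def make_participant_config(
    seed: int,
    n_m1: int = 3,
    n_s1: int = 3,
    n_car_only: int = 6,
    region_lag_s: float = 0.1,
    fs: float = 400.0,
    n_trials_per_finger: int = 30,
    onset_spread_s: float = 0.04,
    jitter_sd: float = 0.05,
    hfb_gain: float = 3.0,
    rise_time_s: float = 0.5,
    **kwargs,
) -> synth.SynthConfig:
    """A cohort-participant config: M1 channels lead S1 by ``region_lag_s``.

    True onsets are evenly spread (zero-mean) within each region, centered
    at -``region_lag_s`` (M1) and 0 (S1), so channels are not exact copies
    of one another while the true region-mean lag is exactly the requested
    value.

    ``n_car_only`` task-silent channels (region ``Other``) pad the CAR pool:
    with only the analysis channels in the reference, the subtracted mean
    carries the task-locked bursts of both regions and pulls the detected
    onsets of M1 and S1 toward each other (real grids reference over the
    full 64-128 channel pool, where this mixing is negligible).

    The default burst rise (0.5 s) keeps every channel's trace on its steep
    rising flank throughout the threshold-optimization window, so the
    optimized threshold - which lands just below the weakest channel's
    in-window maximum - is crossed on the flank rather than at a flat
    plateau, where trial noise would dominate the crossing time.
    """
    regions = ["M1"] * n_m1 + ["S1"] * n_s1 + ["Other"] * n_car_only

    def _spread(k: int) -> np.ndarray:
        if k == 1:
            return np.zeros(1)
        s = np.linspace(-onset_spread_s, onset_spread_s, k)
        return s - s.mean()

    onsets = np.concatenate(
        [-region_lag_s + _spread(n_m1), _spread(n_s1), np.zeros(n_car_only)]
    )
    # Mirrored response durations across regions: heterogeneous trace shapes
    # (as in real data) keep the optimized threshold off the channel maxima,
    # while the region symmetry cancels shape-driven crossing biases in the
    # M1-S1 difference.
    # Hold times chosen so every smoothed burst ends inside the epoch for
    # both regions: a tail clipped by the epoch edge would bias the
    # z-scaling differently for shifted (M1) and unshifted (S1) channels.
    durations = (
        tuple(np.linspace(0.55, 1.15, n_m1))
        + tuple(np.linspace(0.55, 1.15, n_s1))
        + (1.0,) * n_car_only
    )
    return synth.SynthConfig(
        n_channels=n_m1 + n_s1 + n_car_only,
        fs=fs,
        n_trials_per_finger=n_trials_per_finger,
        region_of_channel=tuple(regions),
        true_onset_s=tuple(onsets),
        burst_duration_per_channel=durations,
        modulated_channels=tuple([True] * (n_m1 + n_s1) + [False] * n_car_only),
        reaction_time_jitter_sd=jitter_sd,
        hfb_gain=hfb_gain,
        rise_time_s=rise_time_s,
        seed=seed,
        **kwargs,
    )


def preprocess_and_epoch(cfg: synth.SynthConfig, window=(-1.0, 2.0)):
    """Synthesis through epoching, with MOM alignment from the glove."""
    rec, events, gt = synth.generate_recording(cfg)
    glove = synth.generate_glove(events, gt, cfg)
    rec = preprocess.detect_bad_channels(rec)
    rec = preprocess.common_average_reference(rec)
    rec = preprocess.equalize_filter(rec)
    events = align.detect_mom(glove, events)
    ts = preprocess.epoch(rec, events, window)
    ts = preprocess.reject_trials(ts)
    return ts, gt


def run_participant(
    cfg: synth.SynthConfig,
    band: BandSpec = DEFAULT_BANDS["hfb"],
    search: onset.ThresholdSearch | None = None,
    single_precision: bool = True,
) -> ParticipantResult:
    """Full single-participant pipeline for one band; onsets per finger."""
    search = search or onset.ThresholdSearch()
    ts, gt = preprocess_and_epoch(cfg)
    # CAR-pool-only channels can never qualify for onset analysis; skip
    # their (costly) wavelet transform up front.
    analysis = np.nonzero(
        (ts.channels["in_hand_region"] & ts.channels["region"].isin(["M1", "S1"])).to_numpy()
    )[0]
    if analysis.size:
        ts = ts.select_channels(analysis)
    bp = spectral.compute_band_power(ts, band, single_precision=single_precision)
    stats_df = select.test_task_response(bp)
    keep = select.filter_analysis_channels(stats_df)
    if keep.size == 0:
        raise ValueError(f"no qualifying channels for band {band.name}")
    bp = bp.select_channels(keep)
    bp = onset.smooth_trials(bp)

    full_rows, perm_rows = [], []
    thresholds: dict[str, float] = {}
    for finger in dict.fromkeys(cfg.fingers):  # preserve configured order
        bpf = bp.select_trials(bp.fingers == finger)
        traces = onset.normalize_channels(bpf)
        try:
            thr = onset.optimize_threshold(traces, search)
        except ValueError as exc:
            logger.warning("finger %s skipped: %s", finger, exc)
            continue
        thresholds[finger] = thr
        full_rows.append(onset.detect_onsets(traces, thr, finger))
        thr_perm = onset.optimize_threshold(traces, search, permissive=True)
        perm_rows.append(onset.detect_onsets(traces, thr_perm, finger))

    empty = pd.DataFrame(
        columns=["channel", "finger", "band", "onset_s", "threshold_used", "region", "pre_baseline"]
    )
    return ParticipantResult(
        onsets=pd.concat(full_rows, ignore_index=True) if full_rows else empty,
        onsets_permissive=pd.concat(perm_rows, ignore_index=True) if perm_rows else empty,
        thresholds=thresholds,
        ground_truth=gt,
        n_trials_used=int(bp.n_trials),
    )


def make_gsm_config(
    seed: int,
    n_channels: int = 8,
    n_car_only: int = 6,
    jitter_sd: float = 0.15,
    onset_range_s: tuple[float, float] = (-0.2, 0.22),
    fs: float = 400.0,
    n_trials: int = 40,
    hfb_gain: float = 6.0,
    **kwargs,
) -> synth.SynthConfig:
    """Config for a single-task participant without a usable glove trace:
    large reaction-time jitter, per-channel onsets spread over
    ``onset_range_s`` so relative latencies are non-trivial."""
    regions = tuple(
        ["M1" if i % 2 == 0 else "S1" for i in range(n_channels)] + ["Other"] * n_car_only
    )
    onsets = tuple(np.linspace(*onset_range_s, n_channels)) + (0.0,) * n_car_only
    durations = tuple(np.linspace(0.7, 1.0, n_channels)) + (1.0,) * n_car_only
    return synth.SynthConfig(
        n_channels=n_channels + n_car_only,
        fs=fs,
        n_trials_per_finger=n_trials,
        fingers=("hand",),
        region_of_channel=regions,
        true_onset_s=onsets,
        burst_duration_per_channel=durations,
        modulated_channels=tuple([True] * n_channels + [False] * n_car_only),
        reaction_time_jitter_sd=jitter_sd,
        hfb_gain=hfb_gain,
        seed=seed,
        **kwargs,
    )


def run_gsm_participant(
    cfg: synth.SynthConfig,
    band: BandSpec = DEFAULT_BANDS["hfb"],
    gsm_cfg: align.GsmConfig | None = None,
    search: onset.ThresholdSearch | None = None,
    single_precision: bool = True,
):
    """GSM-aligned pipeline: cue-aligned HFB power selects responsive
    channels and yields per-trial gamma-slope markers; trials are then
    re-epoched on the markers and onsets detected as usual.

    Returns ``(onset_table, ground_truth)``.  HFB significance of the
    selected channels is inherited from the GSM stage (not retested).
    """
    gsm_cfg = gsm_cfg or align.GsmConfig()
    search = search or onset.ThresholdSearch()
    rec, events, gt = synth.generate_recording(cfg)
    rec = preprocess.detect_bad_channels(rec)
    rec = preprocess.common_average_reference(rec)
    rec = preprocess.equalize_filter(rec)

    cue_events = events.copy()
    cue_events["marker_time_s"] = cue_events["cue_time_s"]
    cue_ts = preprocess.epoch(rec, cue_events)
    analysis = np.nonzero(
        (cue_ts.channels["in_hand_region"] & cue_ts.channels["region"].isin(["M1", "S1"]))
        .to_numpy()
    )[0]
    cue_ts = cue_ts.select_channels(analysis)
    cue_bp = spectral.compute_band_power(cue_ts, band, single_precision=single_precision)
    responsive = align.select_responsive_channels_for_gsm(cue_bp, gsm_cfg)
    events = align.detect_gsm(cue_bp, responsive, gsm_cfg, events)

    ts = preprocess.epoch(rec, events)
    ts = ts.select_channels(
        np.nonzero(
            (ts.channels["in_hand_region"] & ts.channels["region"].isin(["M1", "S1"]))
            .to_numpy()
        )[0]
    )
    ts = preprocess.reject_trials(ts)
    bp = spectral.compute_band_power(ts, band, single_precision=single_precision)
    # significance inherited from the GSM selection: restrict to the
    # responsive channels rather than retesting
    bp = bp.select_channels(responsive)
    bp = onset.smooth_trials(bp)
    traces = onset.normalize_channels(bp)
    thr = onset.optimize_threshold(traces, search)
    table = onset.detect_onsets(traces, thr, finger=str(cfg.fingers[0]))
    return table, gt


def run_cohort(
    seed: int,
    n_participants: int = 8,
    band: BandSpec = DEFAULT_BANDS["hfb"],
    region_lag_s: float = 0.1,
    **cfg_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``n_participants`` synthetic participants; returns the stacked
    onset tables (full and permissive variants) with a participant column."""
    full, perm = [], []
    for p in range(n_participants):
        cfg = make_participant_config(seed * 1000 + p, region_lag_s=region_lag_s, **cfg_kwargs)
        res = run_participant(cfg, band=band)
        for df, sink in ((res.onsets, full), (res.onsets_permissive, perm)):
            df = df.copy()
            df.insert(0, "participant", f"S{p + 1:02d}")
            sink.append(df)
    return pd.concat(full, ignore_index=True), pd.concat(perm, ignore_index=True)
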