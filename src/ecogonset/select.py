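"""Task-responsive channel identification and signed-r2 mapping."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import BandPower

logger = logging.getLogger(__name__)

DEFAULT_PRE = (-1.0, -0.5)
DEFAULT_POST = (0.0, 0.5)
ALPHA = 0.05


def _interval_means(bp: BandPower, interval: tuple[float, float]) -> np.ndarray:
    sel = (bp.time_s >= interval[0]) & (bp.time_s <= interval[1])
    if not sel.any():
        raise ValueError(f"interval {interval} outside the epoch")
    return np.nanmean(bp.data[:, :, sel], axis=2)


def test_task_response(
    bp: BandPower,
    pre: tuple[float, float] = DEFAULT_PRE,
    post: tuple[float, float] = DEFAULT_POST,
    alpha: float = ALPHA,
    presumed_significant: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-channel one-sided paired t-test of post- vs pre-marker power.

    Per-trial interval means are paired within trial; the test side is the
    band's expected direction (increase for the high band, decrease
    otherwise).  No multiple-comparison correction is applied.

    ``presumed_significant`` marks channels whose significance was
    inherited from an earlier stage (the GSM alignment special case): for
    those the stored p/t values are still computed but ``significant`` is
    forced True and ``provenance`` records the inheritance.
    """
    if bp.n_trials < 2:
        raise ValueError("need at least 2 trials for a paired test")
    pre_m = _interval_means(bp, pre)
    post_m = _interval_means(bp, post)
    alternative = "greater" if bp.band.direction == "increase" else "less"
    res = stats.ttest_rel(post_m, pre_m, axis=0, alternative=alternative)
    significant = res.pvalue < alpha
    provenance = np.array(["tested"] * bp.n_channels, dtype=object)
    if presumed_significant is not None:
        presumed_significant = np.asarray(presumed_significant, dtype=bool)
        significant = significant | presumed_significant
        provenance[presumed_significant] = "inherited"
    return pd.DataFrame(
        {
            "channel": bp.channels["name"].to_numpy(),
            "band": bp.band.name,
            "t_statistic": res.statistic,
            "p_value": res.pvalue,
            "significant": significant,
            "region": bp.channels["region"].to_numpy(),
            "in_hand_region": bp.channels["in_hand_region"].to_numpy(),
            "provenance": provenance,
        }
    )


def signed_r2(bp: BandPower, design: np.ndarray) -> np.ndarray:
    """Signed coefficient of determination between power and task design.

    ``design`` is an active/rest step function on the trial time axis.
    Per channel, per-trial power samples are concatenated against the tiled
    design vector; the squared Pearson correlation carries the sign of the
    correlation.  Zero-variance channels get 0 with a warning.
    """
    design = np.asarray(design, dtype=float)
    if design.size != bp.time_s.size:
        raise ValueError("design must be defined on the trial time axis")
    out = np.zeros(bp.n_channels)
    y_full = np.tile(design, bp.n_trials)
    for ch in range(bp.n_channels):
        x = bp.data[:, ch, :].ravel()
        ok = np.isfinite(x)
        x, y = x[ok], y_full[ok]
        if x.size < 2 or x.std() == 0 or y.std() == 0:
            logger.warning("zero-variance input for channel %d; signed_r2 = 0", ch)
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[ch] = np.sign(r) * r**2
    return out


def attach_signed_r2(stats_df: pd.DataFrame, r2: np.ndarray) -> pd.DataFrame:
    out = stats_df.copy()
    out["signed_r2"] = r2
    return out


def filter_analysis_channels(stats_df: pd.DataFrame) -> np.ndarray:
    """Channel indices eligible for onset detection in this band.

    Keeps channels that are significant, inside the hand region, and
    labeled M1 or S1 (central-sulcus and other electrodes are excluded on
    purpose: they do not cleanly represent either bank).
    """
    mask = (
        stats_df["significant"].to_numpy()
        & stats_df["in_hand_region"].to_numpy()
        & stats_df["region"].isin(["M1", "S1"]).to_numpy()
    )
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        logger.warning("no qualifying channels for band %s; onset stage will be skipped",
                       stats_df["band"].iloc[0] if len(stats_df) else "?")
    return idx
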