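"""Group-level region timing statistics.

Per-participant/finger region means, a two-within-factor repeated-measures
ANOVA (region x finger, participant as the grouping factor) with
Tukey-adjusted marginal-mean contrasts, per-participant Welch tests with
Bonferroni correction, and earliest-quartile summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ONSET_COLUMNS = ("participant", "channel", "finger", "band", "onset_s", "region")


def summarize_regions(onsets: pd.DataFrame) -> pd.DataFrame:
    """Mean onset and channel count per participant/finger/band/region.

    Output columns: ``mean_onset_M1``, ``mean_onset_S1``, ``n_M1``,
    ``n_S1``; empty cells are NaN (missing), never zero.
    """
    bad = set(onsets["region"]) - {"M1", "S1"}
    if bad:
        raise ValueError(f"unexpected region labels in onset table: {sorted(bad)}")
    rows = []
    for (p, f, b), grp in onsets.groupby(["participant", "finger", "band"], sort=True):
        row = {"participant": p, "finger": f, "band": b}
        for region in ("M1", "S1"):
            vals = grp.loc[grp["region"] == region, "onset_s"].to_numpy()
            row[f"mean_onset_{region}"] = vals.mean() if vals.size else np.nan
            row[f"n_{region}"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Effects table plus Tukey-adjusted post-hoc contrasts."""

    table: pd.DataFrame  # index: effect; columns: F, df1, df2, p
    posthoc: pd.DataFrame
    n_participants: int

    def fmt(self, effect: str) -> str:
        r = self.table.loc[effect]
        return f"F({int(r['df1'])},{int(r['df2'])}) = {r['F']:.2f}, p = {r['p']:.4g}"


def _long_cells(rs: pd.DataFrame) -> pd.DataFrame:
    long = rs.melt(
        id_vars=["participant", "finger"],
        value_vars=["mean_onset_M1", "mean_onset_S1"],
        var_name="region",
        value_name="onset",
    )
    long["region"] = long["region"].str.replace("mean_onset_", "", regex=False)
    return long


def _tukey_p(t: float, k: int, df: int) -> float:
    """Tukey-adjusted p for a pairwise contrast among k marginal means."""
    return float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))


def _pairwise_contrasts(cells: pd.DataFrame, factor: str, value: str = "onset") -> pd.DataFrame:
    """Paired contrasts of per-participant marginal means, Tukey-adjusted."""
    marg = cells.groupby(["participant", factor])[value].mean().unstack(factor)
    levels = list(marg.columns)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = (marg[levels[i]] - marg[levels[j]]).dropna()
            n = len(d)
            res = stats.ttest_rel(marg[levels[i]], marg[levels[j]], nan_policy="omit")
            rows.append(
                {
                    "factor": factor,
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": d.mean(),
                    "t": res.statistic,
                    "df": n - 1,
                    "p_tukey": _tukey_p(res.statistic, k, n - 1),
                }
            )
    return pd.DataFrame(rows)


def region_anova(rs: pd.DataFrame, band: str | None = None, method: str = "rm") -> AnovaResult:
    """Two-within-factor repeated-measures ANOVA on region/finger cell means.

    Participants with incomplete cells are dropped listwise with a warning
    (the classical balanced form needs complete data; for balanced complete
    tables it matches the mixed-effects formulation).  ``method="mixed"``
    fits a random-intercept mixed model instead and reports Wald F tests.
    """
    if band is not None:
        rs = rs.loc[rs["band"] == band]
    cells = _long_cells(rs).dropna(subset=["onset"])
    counts = cells.groupby("participant").size()
    n_cells = cells["region"].nunique() * cells["finger"].nunique()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning("excluding participant(s) with incomplete cells: %s", dropped)
    cells = cells[cells["participant"].isin(complete)]
    n = cells["participant"].nunique()
    if n < 2:
        raise ValueError("need >= 2 participants with complete cells")

    if method == "mixed":
        import statsmodels.formula.api as smf

        model = smf.mixedlm("onset ~ C(region) * C(finger)", cells, groups="participant")
        fit = model.fit(reml=True)
        wald = fit.wald_test_terms(scalar=True)
        table = pd.DataFrame(
            {
                "F": wald.table["statistic"],
                "df1": wald.table["df_constraint"],
                "df2": np.nan,
                "p": wald.table["pvalue"],
            }
        )
        table = table.rename(
            index={
                "C(region)": "region",
                "C(finger)": "finger",
                "C(region):C(finger)": "region:finger",
            }
        )
    elif method == "rm":
        table = _rm_anova_table(cells)
    else:
        raise ValueError("method must be 'rm' or 'mixed'")

    posthoc = pd.concat(
        [_pairwise_contrasts(cells, "region"), _pairwise_contrasts(cells, "finger")],
        ignore_index=True,
    )
    return AnovaResult(table, posthoc, n)


def _rm_anova_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Classical two-within-factor repeated-measures ANOVA.

    Each effect is tested against its interaction with the participant
    factor.  A zero effect sum of squares reports F = 0 and p = 1 even when
    the error term is also degenerate (identical cell values).
    """
    y = cells.pivot_table(index="participant", columns=["region", "finger"],
                          values="onset", sort=True)
    regions = y.columns.get_level_values(0).unique()
    fingers = y.columns.get_level_values(1).unique()
    arr = y.to_numpy().reshape(len(y), len(regions), len(fingers))  # (s, a, b)
    n, a, b = arr.shape
    grand = arr.mean()
    m_a = arr.mean(axis=(0, 2))
    m_b = arr.mean(axis=(0, 1))
    m_s = arr.mean(axis=(1, 2))
    m_ab = arr.mean(axis=0)
    m_as = arr.mean(axis=2)
    m_bs = arr.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    resid = (
        arr
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    # relative floor: rounding dust in an exactly-balanced table must read
    # as a zero effect, not as the ratio of two ~1e-30 sums of squares
    ss_tol = 1e-12 * max(float(np.sum(arr**2)), np.finfo(float).tiny)
    rows = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("region", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("finger", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("region:finger", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        if ss_eff <= ss_tol:
            f_val, p = 0.0, 1.0
        else:
            f_val = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(f_val, df_eff, df_err))
        rows[name] = {"F": f_val, "df1": df_eff, "df2": df_err, "p": p}
    return pd.DataFrame(rows).T


def per_participant_tests(onsets: pd.DataFrame, min_channels: int = 3) -> pd.DataFrame:
    """Welch two-sample t-test of M1 vs S1 onsets per participant/finger.

    Participants with fewer than ``min_channels`` channels in either region
    are excluded from testing and from the Bonferroni correction count; the
    correction factor is the number of tested participants per finger/band.
    """
    rows = []
    for (f, b), fgrp in onsets.groupby(["finger", "band"], sort=True):
        sub = []
        for p, grp in fgrp.groupby("participant", sort=True):
            m1 = grp.loc[grp["region"] == "M1", "onset_s"].to_numpy()
            s1 = grp.loc[grp["region"] == "S1", "onset_s"].to_numpy()
            tested = len(m1) >= min_channels and len(s1) >= min_channels
            row = {
                "participant": p, "finger": f, "band": b,
                "n_M1": len(m1), "n_S1": len(s1), "tested": tested,
                "t": np.nan, "p_raw": np.nan,
            }
            if tested:
                res = stats.ttest_ind(m1, s1, equal_var=False)
                row["t"], row["p_raw"] = res.statistic, res.pvalue
            sub.append(row)
        n_tested = sum(r["tested"] for r in sub)
        for r in sub:
            r["bonferroni_n"] = n_tested
            r["p_corrected"] = min(r["p_raw"] * n_tested, 1.0) if r["tested"] else np.nan
            r["significant"] = bool(r["tested"] and r["p_corrected"] < 0.05)
        rows.extend(sub)
    return pd.DataFrame(rows)


def earliest_quartile_pct(onsets: pd.DataFrame) -> float:
    """Percentage of M1 channels among the earliest quartile of all onsets.

    The quartile holds the earliest ``ceil(n/4)`` channels; ties at the
    boundary onset are all included (which may enlarge the set).
    """
    vals = onsets["onset_s"].to_numpy()
    regions = onsets["region"].to_numpy()
    n = vals.size
    if n < 4:
        raise ValueError("need at least 4 channels for a quartile summary")
    q = math.ceil(n / 4)
    order = np.argsort(vals, kind="stable")
    boundary = vals[order[q - 1]]
    in_set = vals <= boundary
    pct = 100.0 * np.sum(in_set & (regions == "M1")) / np.sum(in_set)
    return float(pct)


def earliest_channel(onsets: pd.DataFrame) -> pd.Series:
    """Row of the channel with the minimal onset; ties go to the first row
    in table order (logged)."""
    if onsets.empty:
        raise ValueError("empty onset table")
    vals = onsets["onset_s"].to_numpy()
    i = int(np.argmin(vals))
    if np.sum(vals == vals[i]) > 1:
        logger.info("earliest-onset tie broken by table order")
    return onsets.iloc[i]


def format_report(result: AnovaResult, summaries: pd.DataFrame, band: str) -> str:
    """Plain-text report of the region comparison for one band."""
    lines = [f"Band: {band}", f"Participants in ANOVA: {result.n_participants}", ""]
    for effect in result.table.index:
        lines.append(f"  {effect}: {result.fmt(effect)}")
    lines.append("")
    lines.append("Post-hoc (Tukey-adjusted marginal-mean contrasts):")
    for _, r in result.posthoc.iterrows():
        lines.append(
            f"  {r['contrast']}: estimate = {r['estimate'] * 1000:.0f} ms, "
            f"t({int(r['df'])}) = {r['t']:.2f}, p = {r['p_tukey']:.4g}"
        )
    lines.append("")
    sub = summaries.loc[summaries["band"] == band] if "band" in summaries else summaries
    for finger, grp in sub.groupby("finger"):
        diff = (grp["mean_onset_M1"] - grp["mean_onset_S1"]).dropna() * 1000
        if len(diff):
            lines.append(
                f"  {finger}: mean M1-S1 difference = {diff.mean():.0f} ms "
                f"+/- {diff.std(ddof=1):.0f} ms (n = {len(diff)})"
            )
    return "\n".join(lines)
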