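import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecogonset import groupstats


def _onset_table(rows):
    return pd.DataFrame(rows, columns=["participant", "channel", "finger", "band",
                                       "onset_s", "region"])


def brute_force_rm_anova(values):
    """Loop-based two-within-factor RM ANOVA sums of squares.

    ``values[s][a][b]`` -> dict of (F, df1, df2) per effect.  Written with
    explicit loops, independently of the package implementation.
    """
    n = len(values)
    a_lv = len(values[0])
    b_lv = len(values[0][0])
    grand = sum(values[s][a][b] for s in range(n) for a in range(a_lv) for b in range(b_lv))
    grand /= n * a_lv * b_lv

    def mean_a(a):
        return sum(values[s][a][b] for s in range(n) for b in range(b_lv)) / (n * b_lv)

    def mean_b(b):
        return sum(values[s][a][b] for s in range(n) for a in range(a_lv)) / (n * a_lv)

    def mean_s(s):
        return sum(values[s][a][b] for a in range(a_lv) for b in range(b_lv)) / (a_lv * b_lv)

    def mean_ab(a, b):
        return sum(values[s][a][b] for s in range(n)) / n

    def mean_as(a, s):
        return sum(values[s][a][b] for b in range(b_lv)) / b_lv

    def mean_bs(b, s):
        return sum(values[s][a][b] for a in range(a_lv)) / a_lv

    ss_a = n * b_lv * sum((mean_a(a) - grand) ** 2 for a in range(a_lv))
    ss_b = n * a_lv * sum((mean_b(b) - grand) ** 2 for b in range(b_lv))
    ss_ab = n * sum(
        (mean_ab(a, b) - mean_a(a) - mean_b(b) + grand) ** 2
        for a in range(a_lv) for b in range(b_lv)
    )
    ss_as = b_lv * sum(
        (mean_as(a, s) - mean_a(a) - mean_s(s) + grand) ** 2
        for a in range(a_lv) for s in range(n)
    )
    ss_bs = a_lv * sum(
        (mean_bs(b, s) - mean_b(b) - mean_s(s) + grand) ** 2
        for b in range(b_lv) for s in range(n)
    )
    ss_abs = sum(
        (values[s][a][b] - mean_ab(a, b) - mean_as(a, s) - mean_bs(b, s)
         + mean_a(a) + mean_b(b) + mean_s(s) - grand) ** 2
        for s in range(n) for a in range(a_lv) for b in range(b_lv)
    )
    out = {}
    out["region"] = (
        (ss_a / (a_lv - 1)) / (ss_as / ((a_lv - 1) * (n - 1))) if ss_a else 0.0,
        a_lv - 1, (a_lv - 1) * (n - 1),
    )
    out["finger"] = (
        (ss_b / (b_lv - 1)) / (ss_bs / ((b_lv - 1) * (n - 1))) if ss_b else 0.0,
        b_lv - 1, (b_lv - 1) * (n - 1),
    )
    df_ab = (a_lv - 1) * (b_lv - 1)
    out["region:finger"] = (
        (ss_ab / df_ab) / (ss_abs / (df_ab * (n - 1))) if ss_ab else 0.0,
        df_ab, df_ab * (n - 1),
    )
    return out


# fixed toy table: 3 participants x 2 regions x 3 fingers (seconds)
TOY_TABLE = [
    # participant 0      thumb   index  little
    [[0.11, 0.15, 0.09],   # M1
     [0.21, 0.24, 0.20]],  # S1
    [[0.08, 0.12, 0.10],
     [0.19, 0.16, 0.22]],
    [[0.14, 0.10, 0.13],
     [0.18, 0.25, 0.17]],
]

FINGERS = ("thumb", "index", "little")


def _toy_summary():
    rows = []
    for s, part in enumerate(TOY_TABLE):
        for a, region in enumerate(("M1", "S1")):
            for b, finger in enumerate(FINGERS):
                rows.append(
                    {"participant": f"P{s}", "finger": finger, "band": "hfb",
                     f"mean_onset_M1": part[0][b], f"mean_onset_S1": part[1][b],
                     "n_M1": 3, "n_S1": 3}
                )
    return pd.DataFrame(rows).drop_duplicates(subset=["participant", "finger"])


class TestSummarizeRegions:
    def test_simple_means(self):
        tab = _onset_table([
            ("P1", "a", "thumb", "hfb", 0.1, "M1"),
            ("P1", "b", "thumb", "hfb", 0.2, "M1"),
            ("P1", "c", "thumb", "hfb", 0.3, "S1"),
        ])
        rs = groupstats.summarize_regions(tab)
        assert rs.loc[0, "mean_onset_M1"] == pytest.approx(0.15)
        assert rs.loc[0, "mean_onset_S1"] == pytest.approx(0.3)
        assert rs.loc[0, "n_M1"] == 2

    def test_empty_cell_is_missing_not_zero(self):
        tab = _onset_table([("P1", "a", "thumb", "hfb", 0.1, "M1")])
        rs = groupstats.summarize_regions(tab)
        assert np.isnan(rs.loc[0, "mean_onset_S1"])
        assert rs.loc[0, "n_S1"] == 0

    def test_unexpected_region_rejected(self):
        tab = _onset_table([("P1", "a", "thumb", "hfb", 0.1, "CS")])
        with pytest.raises(ValueError, match="region"):
            groupstats.summarize_regions(tab)

    def test_injected_region_effect_recovered(self, rng):
        rows = []
        for p in range(8):
            for finger in FINGERS:
                for i in range(5):
                    rows.append((f"P{p}", f"m{i}", finger, "hfb",
                                 rng.normal(-0.1, 0.02), "M1"))
                    rows.append((f"P{p}", f"s{i}", finger, "hfb",
                                 rng.normal(0.0, 0.02), "S1"))
        rs = groupstats.summarize_regions(_onset_table(rows))
        diff = (rs["mean_onset_M1"] - rs["mean_onset_S1"]).mean()
        assert diff == pytest.approx(-0.1, abs=0.02)


class TestRegionAnova:
    def test_identical_cells_give_zero_f(self):
        rs = _toy_summary().copy()
        rs["mean_onset_M1"] = 0.1
        rs["mean_onset_S1"] = 0.1
        res = groupstats.region_anova(rs)
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_matches_brute_force_on_toy_table(self):
        res = groupstats.region_anova(_toy_summary())
        expected = brute_force_rm_anova(TOY_TABLE)
        for effect, (f_val, df1, df2) in expected.items():
            assert res.table.loc[effect, "F"] == pytest.approx(f_val, rel=1e-10)
            assert res.table.loc[effect, "df1"] == df1
            assert res.table.loc[effect, "df2"] == df2

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rs = _toy_summary()
        res = groupstats.region_anova(rs)
        cells = groupstats._long_cells(rs).dropna(subset=["onset"])
        sm_tab = AnovaRM(cells, "onset", "participant", within=["region", "finger"]).fit().anova_table
        for effect, sm_row in zip(("region", "finger", "region:finger"), sm_tab.index):
            assert res.table.loc[effect, "F"] == pytest.approx(
                sm_tab.loc[sm_row, "F Value"], rel=1e-8
            )

    def test_df_match_design(self):
        res = groupstats.region_anova(_toy_summary())
        assert res.table.loc["region", ["df1", "df2"]].tolist() == [1, 2]
        assert res.table.loc["finger", ["df1", "df2"]].tolist() == [2, 4]
        assert res.table.loc["region:finger", ["df1", "df2"]].tolist() == [2, 4]

    def test_incomplete_participant_dropped(self):
        rs = _toy_summary()
        rs.loc[(rs["participant"] == "P2") & (rs["finger"] == "thumb"),
               "mean_onset_S1"] = np.nan
        res = groupstats.region_anova(rs)
        assert res.n_participants == 2

    def test_power_with_injected_effect(self, rng):
        # region effect -100 ms, between-participant SD 40 ms, 8 participants
        hits = 0
        reps = 100
        for _ in range(reps):
            rows = []
            for p in range(8):
                d = rng.normal(-0.1, 0.04)
                for finger in FINGERS:
                    base = rng.normal(0.3, 0.02)
                    rows.append({"participant": f"P{p}", "finger": finger, "band": "hfb",
                                 "mean_onset_M1": base + d + rng.normal(0, 0.01),
                                 "mean_onset_S1": base + rng.normal(0, 0.01),
                                 "n_M1": 3, "n_S1": 3})
            res = groupstats.region_anova(pd.DataFrame(rows))
            hits += int(res.table.loc["region", "p"] < 0.05)
        assert hits / reps >= 0.9

    def test_posthoc_region_contrast_matches_paired_t(self):
        rs = _toy_summary()
        res = groupstats.region_anova(rs)
        row = res.posthoc[res.posthoc["factor"] == "region"].iloc[0]
        marg = groupstats._long_cells(rs).groupby(["participant", "region"])["onset"].mean().unstack()
        t_ref = stats.ttest_rel(marg["M1"], marg["S1"])
        assert row["t"] == pytest.approx(t_ref.statistic)
        # Tukey with k=2 equals the two-sided paired t
        assert row["p_tukey"] == pytest.approx(t_ref.pvalue, rel=1e-6)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings("ignore:.*boundary.*")
    def test_mixed_method_runs(self):
        res = groupstats.region_anova(_toy_summary(), method="mixed")
        assert "region" in res.table.index
        assert res.table.loc["region", "p"] < 0.05


class TestPerParticipantTests:
    def _table(self, n_m1, n_s1, sep=0.15, sd=0.05, rng=None, participant="P1"):
        rng = rng or np.random.default_rng(0)
        rows = [(participant, f"m{i}", "thumb", "hfb", rng.normal(-sep, sd), "M1")
                for i in range(n_m1)]
        rows += [(participant, f"s{i}", "thumb", "hfb", rng.normal(0.0, sd), "S1")
                 for i in range(n_s1)]
        return _onset_table(rows)

    def test_small_region_excluded(self, rng):
        tab = pd.concat([self._table(2, 10, rng=rng, participant="P1"),
                         self._table(10, 10, rng=rng, participant="P2")])
        res = groupstats.per_participant_tests(tab)
        assert not res.loc[res["participant"] == "P1", "tested"].iloc[0]
        assert res.loc[res["participant"] == "P2", "tested"].iloc[0]
        assert (res["bonferroni_n"] == 1).all()

    def test_identical_distributions_not_significant(self, rng):
        rows = [("P1", f"m{i}", "thumb", "hfb", v, "M1") for i, v in enumerate([0.1, 0.2, 0.3, 0.4])]
        rows += [("P1", f"s{i}", "thumb", "hfb", v, "S1") for i, v in enumerate([0.1, 0.2, 0.3, 0.4])]
        res = groupstats.per_participant_tests(_onset_table(rows))
        assert not res["significant"].iloc[0]

    def test_separation_detected_after_correction(self, rng):
        # injected 150 ms separation, 10+10 channels, SD 50 ms
        hits = 0
        reps = 60
        for r in range(reps):
            tab = pd.concat([self._table(10, 10, rng=rng, participant=f"P{k}")
                             for k in range(5)])
            res = groupstats.per_participant_tests(tab)
            hits += int(res["significant"].all())
        assert hits / reps >= 0.9


class TestEarliestQuartile:
    def test_three_m1_earliest_of_twelve(self):
        rows = [("P1", f"m{i}", "t", "hfb", 0.1 + 0.01 * i, "M1") for i in range(3)]
        rows += [("P1", f"s{i}", "t", "hfb", 0.5 + 0.01 * i, "S1") for i in range(9)]
        assert groupstats.earliest_quartile_pct(_onset_table(rows)) == 100.0

    def test_alternating_onsets_give_half(self):
        rows = []
        for i in range(8):
            rows.append(("P1", f"m{i}", "t", "hfb", 0.1 + 0.02 * i, "M1"))
            rows.append(("P1", f"s{i}", "t", "hfb", 0.11 + 0.02 * i, "S1"))
        assert groupstats.earliest_quartile_pct(_onset_table(rows)) == 50.0

    def test_all_m1_earlier(self):
        rows = [("P1", f"m{i}", "t", "hfb", 0.1 + 0.01 * i, "M1") for i in range(8)]
        rows += [("P1", f"s{i}", "t", "hfb", 0.3 + 0.01 * i, "S1") for i in range(8)]
        assert groupstats.earliest_quartile_pct(_onset_table(rows)) == 100.0

    def test_boundary_ties_all_included_and_order_invariant(self):
        # quartile size 2 of 8, but three channels tie at the boundary value
        base = [("P1", "a", "t", "hfb", 0.10, "M1"),
                ("P1", "b", "t", "hfb", 0.12, "M1"),
                ("P1", "c", "t", "hfb", 0.12, "S1"),
                ("P1", "d", "t", "hfb", 0.12, "S1"),
                ("P1", "e", "t", "hfb", 0.30, "S1"),
                ("P1", "f", "t", "hfb", 0.31, "S1"),
                ("P1", "g", "t", "hfb", 0.32, "S1"),
                ("P1", "h", "t", "hfb", 0.33, "S1")]
        values = {groupstats.earliest_quartile_pct(_onset_table(list(perm)))
                  for perm in itertools.permutations(base, len(base))
                  if perm[0][1] == "a"}  # fix one element; 5040 permutations
        assert values == {50.0}  # 2 M1 of the enlarged 4-channel set

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            groupstats.earliest_quartile_pct(
                _onset_table([("P1", "a", "t", "hfb", 0.1, "M1")])
            )

    def test_bounds(self, rng):
        rows = [("P1", f"c{i}", "t", "hfb", rng.uniform(), rng.choice(["M1", "S1"]))
                for i in range(17)]
        pct = groupstats.earliest_quartile_pct(_onset_table(rows))
        assert 0.0 <= pct <= 100.0


class TestEarliestChannel:
    def test_unique_minimum(self):
        tab = _onset_table([("P1", "a", "t", "hfb", 0.3, "S1"),
                            ("P1", "b", "t", "hfb", 0.1, "M1")])
        row = groupstats.earliest_channel(tab)
        assert row["channel"] == "b"
        assert row["region"] == "M1"

    def test_tie_broken_by_order(self):
        tab = _onset_table([("P1", "a", "t", "hfb", 0.1, "S1"),
                            ("P1", "b", "t", "hfb", 0.1, "M1")])
        assert groupstats.earliest_channel(tab)["channel"] == "a"

    def test_empty_table(self):
        with pytest.raises(ValueError):
            groupstats.earliest_channel(_onset_table([]))


class TestReport:
    def test_format_report_contains_effects(self):
        rs = _toy_summary()
        res = groupstats.region_anova(rs)
        text = groupstats.format_report(res, rs, "hfb")
        assert "region" in text and "F(1,2)" in text
        assert "M1 - S1" in text
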