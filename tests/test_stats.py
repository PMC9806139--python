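import numpy as np
import pandas as pd
import pytest

import ratgait as rg


def make_long(g, t, n_per_group, rng, group_effect=0.0, time_effect=0.0, inter=0.0):
    rows = []
    for gi in range(g):
        for si in range(n_per_group[gi] if isinstance(n_per_group, (list, tuple)) else n_per_group):
            subj = f"g{gi}s{si}"
            b = rng.normal(0.0, 1.0)
            for ti in range(t):
                rows.append(
                    {
                        "subject": subj,
                        "group": f"g{gi}",
                        "day": f"t{ti}",
                        "value": gi * group_effect
                        + ti * time_effect
                        + gi * ti * inter
                        + b
                        + rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


def brute_force_splitplot(df):
    """Per-observation mean-decomposition of the split-plot sums of squares."""
    grand = df.value.mean()
    mg = df.groupby("group").value.mean()
    mt = df.groupby("day").value.mean()
    mgt = df.groupby(["group", "day"]).value.mean()
    ms_ = df.groupby("subject").value.mean()
    ss = {"group": 0.0, "time": 0.0, "time:group": 0.0, "subj": 0.0, "error": 0.0}
    for _, r in df.iterrows():
        gm, tm, cm, sm = mg[r.group], mt[r.day], mgt[(r.group, r.day)], ms_[r.subject]
        ss["group"] += (gm - grand) ** 2
        ss["time"] += (tm - grand) ** 2
        ss["time:group"] += (cm - gm - tm + grand) ** 2
        ss["subj"] += (sm - gm) ** 2
        ss["error"] += (r.value - cm - sm + gm) ** 2
    return ss


class TestMixedAnova:
    def test_four_by_six_design_degrees_of_freedom(self):
        df = make_long(4, 6, [5, 5, 9, 6], np.random.default_rng(0))
        tab = rg.mixed_anova(df)
        assert tab.terms["group"].df_num == 3
        assert tab.terms["time"].df_num == 5
        assert tab.terms["time:group"].df_num == 15
        assert tab.terms["group"].df_den == 25 - 4
        assert tab.terms["time:group"].df_den == (25 - 4) * 5

    @pytest.mark.parametrize("g,t,n", [(2, 2, 3), (3, 5, 4), (4, 3, 2)])
    def test_matches_mean_decomposition_oracle(self, g, t, n):
        df = make_long(g, t, n, np.random.default_rng(g * 10 + t), 0.5, 0.3, 0.2)
        tab = rg.mixed_anova(df)
        oracle = brute_force_splitplot(df)
        assert tab.terms["group"].ss == pytest.approx(oracle["group"], rel=1e-9)
        assert tab.terms["time"].ss == pytest.approx(oracle["time"], rel=1e-9)
        assert tab.terms["time:group"].ss == pytest.approx(oracle["time:group"], rel=1e-9)
        assert tab.ss_subjects == pytest.approx(oracle["subj"], rel=1e-9)
        assert tab.ss_error == pytest.approx(oracle["error"], rel=1e-9)

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        df = make_long(3, 4, 5, np.random.default_rng(3), 0.8, 0.2, 0.1)
        ours = rg.mixed_anova(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="day", between="group", subject="subject"
        ).set_index("Source")
        assert ours.terms["group"].f == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours.terms["time"].f == pytest.approx(ref.loc["day", "F"], rel=1e-9)
        assert ours.terms["time:group"].f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert ours.terms["time:group"].p == pytest.approx(ref.loc["Interaction", "p_unc"], rel=1e-9)

    def test_constant_data_has_zero_total_ss_and_undefined_f(self):
        df = make_long(2, 3, 3, np.random.default_rng(0))
        df["value"] = 7.0
        tab = rg.mixed_anova(df)
        assert tab.terms["group"].ss == pytest.approx(0.0, abs=1e-18)
        assert np.isnan(tab.terms["group"].f)

    def test_incomplete_subject_dropped_listwise(self, caplog):
        df = make_long(2, 3, 4, np.random.default_rng(1))
        df = df[~((df.subject == "g0s0") & (df.day == "t2"))]
        with caplog.at_level("WARNING"):
            tab = rg.mixed_anova(df)
        assert tab.n_subjects == 7
        assert tab.dropped_subjects == ["g0s0"]

    def test_single_group_rejected(self):
        df = make_long(1, 3, 4, np.random.default_rng(0))
        with pytest.raises(rg.InsufficientDataError):
            rg.mixed_anova(df)


class TestLsdPosthoc:
    def test_equal_means_give_t_zero_p_one(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3 + ["b"] * 3, "value": [1.0, 2.0, 3.0] * 2}
        )
        out = rg.lsd_posthoc(df, require_significant_omnibus=False)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_three_groups_give_three_contrasts(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"group": np.repeat(["a", "b", "c"], 4), "value": rng.normal(size=12)}
        )
        assert len(rg.lsd_posthoc(df)) == 3

    def test_external_error_term_requires_df(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "value": [1, 2, 3, 4.0]})
        with pytest.raises(rg.InvalidParameterError):
            rg.lsd_posthoc(df, ms_error=1.0)

    def test_detects_toe_spread_deficit_at_day1(self):
        """Combined-lesion vs sham toe spread separates clearly on day 1."""
        design = rg.CohortDesign(group_sizes={"sham": 5, "L5L6": 6}, days=("d1",))
        gait, _ = rg.summarize_recordings(rg.simulate_cohort(design, seed=0))
        sub = gait[
            (gait.limb == "right") & (gait.metric == "toe_spread_mm") & gait.valid
        ]
        out = rg.lsd_posthoc(sub, require_significant_omnibus=False)
        assert out.loc[0, "p"] < 0.05
        assert abs(out.loc[0, "mean_diff"]) > 3.0


class TestOnewayBonferroni:
    def test_fifteen_contrasts_for_six_time_points(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"day": np.repeat([f"d{i}" for i in range(6)], 4), "value": rng.normal(size=24)}
        )
        out = rg.oneway_bonferroni(df)
        assert len(out) == 15
        assert (out.p_bonf >= out.p_raw - 1e-12).all()
        assert (out.p_bonf <= 1.0).all()

    def test_identical_means_give_zero_omnibus_f(self):
        df = pd.DataFrame({"day": ["a"] * 3 + ["b"] * 3, "value": [1.0, 2.0, 3.0] * 2})
        out = rg.oneway_bonferroni(df)
        assert out.loc[0, "omnibus_F"] == pytest.approx(0.0)

    def test_single_time_point_rejected(self):
        df = pd.DataFrame({"day": ["a"] * 4, "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(rg.InsufficientDataError):
            rg.oneway_bonferroni(df)
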