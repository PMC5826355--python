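import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

from shoremaps.inference import (
    compare_deltas,
    delta_tp,
    group_delta_tests,
    mixed_anova,
    posthoc,
    rm_anova,
    stars,
)
from shoremaps.phantom import CohortSpec, DEFAULT_EFFECT_PROFILE, simulate_measure_table


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["subject", "group", "session", "unit_type", "unit_id", "index", "value"]
    )


class TestDelta:
    def _table(self, v1, v2):
        return make_table(
            [
                ("s1", "patient", 1, "connection", "CC:CC-M1", "fa", v1),
                ("s1", "patient", 2, "connection", "CC:CC-M1", "fa", v2),
            ]
        )

    def test_no_change_is_zero(self):
        assert delta_tp(self._table(5.0, 5.0), (1, 2))["delta_pct"].iloc[0] == 0.0

    def test_ten_to_twelve_is_twenty_percent(self):
        assert delta_tp(self._table(10.0, 12.0), (1, 2))["delta_pct"].iloc[0] == pytest.approx(20.0)

    def test_sign_insensitive(self):
        d = delta_tp(self._table(12.0, 10.0), (1, 2))["delta_pct"].iloc[0]
        assert d == pytest.approx(100 * 2 / 12)
        assert d > 0

    def test_nonpositive_baseline_dropped(self, caplog):
        table = pd.concat([self._table(10.0, 12.0), make_table(
            [
                ("s2", "patient", 1, "connection", "CC:CC-M1", "fa", 0.0),
                ("s2", "patient", 2, "connection", "CC:CC-M1", "fa", 2.0),
            ]
        )])
        out = delta_tp(table, (1, 2))
        assert len(out) == 1


class TestCompareDeltas:
    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5, 1, 10)
        b = rng.normal(8, 1, 10)
        res = compare_deltas(a, b, n_indices=7)
        assert res["p_adj"] == pytest.approx(min(1.0, res["p"] * 7))

    def test_null_split_not_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5, 1, 20)
        res = compare_deltas(x[:10], x[10:], n_indices=7)
        assert res["p_adj"] > 0.05

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            compare_deltas([1.0, 1.0], [1.0, 1.0])

    def test_stars_levels(self):
        assert stars(0.04) == "*"
        assert stars(0.004) == "**"
        assert stars(0.0004) == "***"
        assert stars(0.2) == ""


class TestInjectedEffectRecovery:
    def test_anisotropy_elevation_detected_after_bonferroni(self, cohort):
        """The injected tp1 anisotropy elevation in patients produces a
        significant control-vs-patient Delta(tp1, tp2) difference after
        Bonferroni correction across the seven indices."""
        measures, _ = cohort
        tests = group_delta_tests(measures, n_indices=7)
        row = tests[
            (tests["index"] == "gfa") & (tests["loop"] == "SUBCORT") & (tests["pair"] == "tp12")
        ].iloc[0]
        assert row["p_adj"] < 0.05
        assert row["mean_patient"] > row["mean_control"]
        assert row["ks_p_control"] > 0.05  # normality not rejected


def random_rm_table(rng, n_subj=6, na=3, nb=4):
    rows = []
    for s in range(n_subj):
        for a in range(na):
            for b in range(nb):
                rows.append((f"s{s}", a, f"u{b}", rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "session", "unit_id", "value"])


class TestRmAnova:
    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_statsmodels_anovarm(self, seed):
        """F statistics and dfs agree with the independent AnovaRM
        implementation on random balanced data."""
        rng = np.random.default_rng(seed)
        df = random_rm_table(rng)
        ours = rm_anova(df)
        ref = AnovaRM(
            df, depvar="value", subject="subject", within=["session", "unit_id"]
        ).fit().anova_table
        for effect, key in [("TP", "session"), ("ROI", "unit_id"), ("TP*ROI", "session:unit_id")]:
            assert ours[effect].f == pytest.approx(ref.loc[key, "F Value"], rel=1e-8)
            assert ours[effect].df1 == ref.loc[key, "Num DF"]
            assert ours[effect].df2 == ref.loc[key, "Den DF"]

    def test_interaction_df_with_emulated_design(self, cohort):
        measures, _ = cohort
        pat = measures[
            (measures["group"] == "patient")
            & (measures["unit_type"] == "roi")
            & (measures["index"] == "fa")
        ]
        res = rm_anova(pat)
        assert (res["TP*ROI"].df1, res["TP*ROI"].df2) == (70, 630)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        df = random_rm_table(rng)
        shifted = df.assign(value=df["value"] + 100.0)
        a, b = rm_anova(df), rm_anova(shifted)
        for effect in ("TP", "ROI", "TP*ROI"):
            assert a[effect].f == pytest.approx(b[effect].f, rel=1e-9)

    def test_null_f_near_one_in_expectation(self):
        rng = np.random.default_rng(10)
        fs = [rm_anova(random_rm_table(rng))["TP*ROI"].f for _ in range(100)]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)


def mixed_table(rng, n_per=5, na=2, nb=3, group_shift=0.0):
    rows = []
    for g, gname in enumerate(["control", "patient"]):
        for s in range(n_per):
            for a in range(na):
                for b in range(nb):
                    rows.append(
                        (f"{gname}{s}", gname, a, f"u{b}", rng.normal() + g * group_shift)
                    )
    return pd.DataFrame(rows, columns=["subject", "group", "session", "unit_id", "value"])


class TestMixedAnova:
    def test_ss_partition_exact(self):
        """All effect and error SS sum to the total SS on a 2x2x3 toy."""
        rng = np.random.default_rng(1)
        df = mixed_table(rng)
        tab = mixed_anova(df)
        y = tab.data
        ss_total = float(np.sum((y - y.mean()) ** 2))
        eff = sum(r.ss for r in tab.results.values())
        err = sum(ss for ss, _ in tab.error_terms.values())
        assert eff + err == pytest.approx(ss_total, rel=1e-9)
        # degrees of freedom partition as well
        df_eff = sum(r.df1 for r in tab.results.values())
        df_err = sum(d for _, d in tab.error_terms.values())
        assert df_eff + df_err == y.size - 1

    def test_group_df_and_interaction_df(self, cohort):
        measures, _ = cohort
        sub = measures[
            (measures["unit_type"] == "roi")
            & (measures["index"] == "gfa")
            & (measures["session"].isin([1, 2]))
        ]
        tab = mixed_anova(sub)
        assert (tab["Group"].df1, tab["Group"].df2) == (1, 18)
        assert (tab["Group*TP*ROI"].df1, tab["Group*TP*ROI"].df2) == (35, 630)
        assert (tab["Group*ROI"].df1, tab["Group*ROI"].df2) == (35, 630)

    def test_two_level_within_factor_sphericity_trivial(self):
        rng = np.random.default_rng(4)
        df = mixed_table(rng, nb=3)
        tab = mixed_anova(df)
        assert tab["TP"].epsilon == 1.0  # two sessions -> one contrast
        assert tab["TP"].p_gg is None

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(6)
        df = mixed_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells|unbalanced"):
            mixed_anova(df)

    def test_group_effect_type_i_calibration(self):
        """Null cohorts: the Group test rejects at ~ the nominal 5% rate
        (200 replicates, 6 regions)."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = mixed_table(rng, n_per=10, na=2, nb=6)
            if mixed_anova(df)["Group"].p < 0.05:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)


class TestPosthoc:
    def test_gate_refusal_on_nonsignificant_interaction(self):
        rng = np.random.default_rng(9)
        tab = mixed_anova(mixed_table(rng))
        if tab["Group*TP*ROI"].p_report < 0.05:
            pytest.skip("random table happened to be significant")
        with pytest.raises(ValueError, match="not significant"):
            posthoc(tab)

    def test_bonferroni_subset_of_lsd(self, cohort):
        measures, _ = cohort
        sub = measures[
            (measures["unit_type"] == "roi")
            & (measures["index"] == "gfa")
            & (measures["session"].isin([1, 2]))
        ]
        tab = mixed_anova(sub)
        bon = posthoc(tab, method="bonferroni")
        lsd = posthoc(tab, method="lsd")
        sig_bon = set(map(tuple, bon[bon.significant][["unit", "comparison"]].to_numpy()))
        sig_lsd = set(map(tuple, lsd[lsd.significant][["unit", "comparison"]].to_numpy()))
        assert sig_bon <= sig_lsd
        # LSD p-values are the raw ones; Bonferroni multiplies by the family
        merged = bon.merge(lsd, on=["unit", "comparison"], suffixes=("_b", "_l"))
        assert (merged["p_adj_b"] >= merged["p_adj_l"] - 1e-12).all()

    def test_rm_posthoc_detects_tp1_elevation(self, cohort):
        """Patient-only RM post-hoc: the injected tp1 anisotropy
        elevation shows as tp1 > tp2 in affected regions."""
        measures, _ = cohort
        pat = measures[
            (measures["group"] == "patient")
            & (measures["unit_type"] == "roi")
            & (measures["index"] == "gfa")
        ]
        tab = rm_anova(pat)
        res = posthoc(tab, method="lsd")
        sig = res[(res["comparison"] == "tp1 vs tp2") & res.significant]
        assert (sig["sign"] > 0).any()
        assert set(sig[sig["sign"] > 0]["unit"]) & {"M1", "SMA", "PM", "Thl"}
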