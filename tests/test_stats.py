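"""Hypothesis tests, correlations and FDR adjustment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tpdcnet as t


def make_cohort_sessions(seed=0, n=12):
    co = t.simulate_cohort(t.CohortSpec(n_per_group=n, seed=seed))
    pd_rows = co[co.group == "PD"]
    return (pd_rows[pd_rows.session == "baseline"],
            pd_rows[pd_rows.session == "follow-up"])


class TestDeltaEC:
    def test_identical_sessions_give_zero(self):
        base, _ = make_cohort_sessions()
        d = t.delta_ec(base, base)
        feats = [c for c in d.columns if c != "subject_id"]
        assert (d[feats] == 0).all().all()

    def test_sign_convention_baseline_minus_followup(self):
        base = pd.DataFrame({"subject_id": ["s1"], "PFC->MC": [0.5]})
        fu = pd.DataFrame({"subject_id": ["s1"], "PFC->MC": [0.3]})
        d = t.delta_ec(base, fu)
        assert d.loc[0, "PFC->MC"] == pytest.approx(0.2)

    def test_swapping_sessions_negates(self):
        base, fu = make_cohort_sessions(seed=3)
        a = t.delta_ec(base, fu)
        b = t.delta_ec(fu, base)
        feats = [c for c in a.columns if c != "subject_id"]
        assert np.allclose(a[feats].to_numpy(), -b[feats].to_numpy())

    def test_unmatched_subjects_excluded_with_warning(self, caplog):
        import logging

        base, fu = make_cohort_sessions(seed=4)
        fu = fu[fu.subject_id != "PD01"]
        with caplog.at_level(logging.WARNING, logger="tpdcnet.stats"):
            d = t.delta_ec(base, fu)
        assert "PD01" not in d.subject_id.tolist()
        assert any("excluded" in r.message for r in caplog.records)


def make_walking(seed, between_shift=0.0, n=19):
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in (("PD", between_shift), ("HC", 0.0)):
        subj = rng.normal(size=n)
        for i in range(n):
            for cond in ("NW", "DT"):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "condition": cond,
                             "prefrontal_ec": shift + subj[i] + rng.normal()})
    return pd.DataFrame(rows)


class TestNpTwoWayAnova:
    def test_constant_shift_invariance(self):
        df = make_walking(0)
        a = t.np_two_way_anova(df, "prefrontal_ec", "group", "condition",
                               "subject_id")
        df2 = df.copy()
        df2["prefrontal_ec"] += 1000.0
        b = t.np_two_way_anova(df2, "prefrontal_ec", "group", "condition",
                               "subject_id")
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_strong_between_effect_detected(self):
        hits = 0
        for seed in range(20):
            df = make_walking(seed, between_shift=2.0)
            aov = t.np_two_way_anova(df, "prefrontal_ec", "group",
                                     "condition", "subject_id")
            hits += aov.loc["between", "p"] < 0.05
        assert hits >= 18

    def test_art_method_agrees_on_strong_effect(self):
        df = make_walking(1, between_shift=2.0)
        aov = t.np_two_way_anova(df, "prefrontal_ec", "group", "condition",
                                 "subject_id", method="art")
        assert aov.loc["between", "p"] < 0.05
        assert set(aov.index) == {"between", "within", "interaction"}

    def test_empty_cell_rejected(self):
        df = make_walking(0)
        df = df[~((df.group == "PD") & (df.condition == "DT"))]
        with pytest.raises(t.TpdcError):
            t.np_two_way_anova(df, "prefrontal_ec", "group", "condition",
                               "subject_id")


class TestRankTests:
    def test_paired_t_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        stat, p = t.paired_t(x, x)
        assert stat == 0.0 and p == 1.0

    def test_mwu_exact_separated_samples(self):
        u, p = t.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # brute-force enumeration over all C(6,3)=20 group assignments
        vals = [1, 2, 3, 4, 5, 6]
        us = []
        for c in combinations(range(6), 3):
            a = [vals[i] for i in c]
            b = [vals[i] for i in range(6) if i not in c]
            us.append(sum(x > y_ for x in a for y_ in b))
        us = np.array(us)
        p_brute = np.mean(us <= 0) * 2
        assert p == pytest.approx(p_brute)  # 0.1

    def test_wilcoxon_balanced_differences_null_midpoint(self):
        stat, p = t.wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0]))
        # brute-force enumeration of all 2^4 sign assignments
        ranks = np.array([1.5, 1.5, 3.5, 3.5])
        ws = [np.sum(ranks[list(signs)]) for signs in
              [[i for i in range(4) if (mask >> i) & 1] for mask in range(16)]]
        assert stat == pytest.approx(np.median(ws))  # null midpoint 5
        assert p > 0.9

    def test_wilcoxon_degenerate_zero_differences(self):
        with pytest.raises(t.TpdcError, match="zero"):
            t.wilcoxon_signed_rank(np.zeros(5))

    def test_rank_tests_monotone_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=12)
        u1, p1 = t.mann_whitney_u(a, b)
        u2, p2 = t.mann_whitney_u(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)
        rho1, ps1 = t.spearman_corr(a, b)
        rho2, ps2 = t.spearman_corr(np.exp(a), b)
        assert rho1 == pytest.approx(rho2) and ps1 == pytest.approx(ps2)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.1, 0.5, 1.2, 3.0, 4.5])
        rho, _ = t.spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _ = t.spearman_corr(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        rho, _ = t.spearman_corr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*2/(5*24)

    def test_constant_input_rejected(self):
        with pytest.raises(t.TpdcError, match="constant"):
            t.spearman_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPowerTransformPearson:
    def test_normal_inputs_skip_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = t.power_transform_pearson(x, y)
        assert not res["x"]["transformed"] and not res["y"]["transformed"]
        from scipy.stats import pearsonr

        r_ref, _ = pearsonr(x, y)
        assert res["r"] == pytest.approx(r_ref)

    def test_exact_linear_relation_keeps_r_one(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(size=50))  # non-normal, positive
        y = 2.0 + 3.0 * x
        res = t.power_transform_pearson(x, x * 0 + y, alpha=0.0)  # gate off
        assert res["r"] == pytest.approx(1.0)

    def test_lognormal_transform_improves_correlation(self):
        from scipy.stats import pearsonr

        improved = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.normal(size=40))
            y = 0.8 * np.log(x) + 0.3 * rng.normal(size=40)
            raw_r, _ = pearsonr(x, y)
            res = t.power_transform_pearson(x, y)
            improved += abs(res["r"]) >= abs(raw_r)
        assert improved / reps >= 0.9

    def test_strict_mode_rejects_nonpositive(self):
        x = np.array([0.0] + list(np.exp(np.random.default_rng(2).normal(size=30))))
        with pytest.raises(t.TpdcError, match="non-positive"):
            t.power_transform_pearson(x, np.arange(31.0), strict=True)


class TestFDR:
    def test_single_p_unchanged(self):
        assert t.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(t.fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_rule_hand_example(self):
        adj = t.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=15))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = t.fdr_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(t.TpdcError):
            t.fdr_adjust([0.5, 1.2])


class TestBatteries:
    def test_resting_ec_report_complete(self):
        co = t.simulate_cohort(t.CohortSpec(n_per_group=10, seed=2))
        # perturb so Wilcoxon differences are not identically zero
        rep = t.battery_resting_ec(co)
        # 20 MWU + 20 Wilcoxon rows, each exactly once
        assert len(rep.table) == 40
        assert (rep.table["p_fdr"] + 1e-12 >= rep.table["p_raw"]).all()
        assert rep.table["effect"].is_unique

    def test_prefrontal_anova_battery(self):
        rep = t.battery_prefrontal_anova(make_walking(0))
        assert set(rep.table["effect"]) == {"between", "within", "interaction"}

    def test_delta_corr_battery(self):
        base, fu = make_cohort_sessions(seed=5)
        d = t.delta_ec(base, fu)
        rep = t.battery_delta_corr(d, [("CB->SC", "MC->SC"),
                                       ("BS->MC", "SC->MC")])
        assert len(rep.table) == 2

    def test_covariate_battery(self):
        co = t.simulate_cohort(t.CohortSpec(n_per_group=12, seed=6))
        rng = np.random.default_rng(0)
        co["UPDRS"] = rng.normal(50, 10, size=len(co))
        rep = t.battery_covariate_corr(co, "UPDRS",
                                       feature_cols=["CB->SC", "MC->SC"])
        assert len(rep.table) == 2
        assert (rep.table["n"] == 12).all()
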