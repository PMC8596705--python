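"""Cohort-statistics tests: exact arithmetic, frozen split-plot oracle,
enumeration oracle for the signed-rank test, calibration by simulation."""

import numpy as np
import pandas as pd
import pytest
from itertools import product

from hrdquant import study
from hrdquant.cohort_stats import (
    normality_check,
    one_way_time_anova,
    paired_wilcoxon,
    percent_change,
    percent_change_summary,
    rm_anova,
    subgroup_medians,
    summarize,
)
from hrdquant.synthetic import CohortParams, simulate_cohort


def tidy(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "timepoint", "count"])


@pytest.fixture
def toy_splitplot():
    """2 groups x 3 subjects x 2 timepoints with hand-checkable sums of squares."""
    data = {"A": [(8, 10), (9, 13), (7, 11)], "B": [(12, 16), (14, 19), (13, 18)]}
    rows = []
    for g, subs in data.items():
        for i, (t1, t2) in enumerate(subs):
            rows += [(f"{g}{i+1}", g, "t1", t1), (f"{g}{i+1}", g, "t2", t2)]
    return tidy(rows)


class TestPercentChange:
    def test_simple_arithmetic(self):
        c = tidy([("s1", "g", "T0", 800), ("s1", "g", "T1", 600),
                  ("s2", "g", "T0", 500), ("s2", "g", "T1", 500)])
        pc = percent_change(c).set_index(["subject", "timepoint"])["pct_change"]
        assert pc[("s1", "T1")] == pytest.approx(-25.0)
        assert pc[("s2", "T1")] == pytest.approx(0.0)
        assert pc[("s1", "T0")] == 0.0

    def test_zero_baseline_reported_missing(self):
        c = tidy([("s1", "g", "T0", 0), ("s1", "g", "T1", 5),
                  ("s2", "g", "T0", 10), ("s2", "g", "T1", 5)])
        pc = percent_change(c)
        assert pc[pc.subject == "s1"]["pct_change"].isna().all()
        summ = percent_change_summary(c)
        assert (summ[summ.timepoint == "T1"]["n"] == 1).all()

    def test_group_mean_recovers_published_bleach_change(self):
        """Default simulated cohorts: Group-1 mean percent change right after
        the photobleach averages to about -25.1% over 200 cohorts."""
        vals = []
        for s in range(200):
            cohort, _ = simulate_cohort(CohortParams(seed=40_000 + s))
            summ = percent_change_summary(cohort)
            vals.append(float(summ[(summ.group == "group1") & (summ.timepoint == "T22_bleach")]["mean"].iloc[0]))
        assert np.mean(vals) == pytest.approx(-25.1, abs=1.0)

    def test_commutes_with_subject_relabelling(self):
        cohort, _ = simulate_cohort(CohortParams(seed=77))
        relabel = {s: f"x{i}" for i, s in enumerate(cohort["subject"].unique())}
        shuffled = cohort.copy()
        shuffled["subject"] = shuffled["subject"].map(relabel)
        a = percent_change_summary(cohort).drop(columns=[]).reset_index(drop=True)
        b = percent_change_summary(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSummarize:
    def test_equal_n_pooling_is_mean_of_group_means(self):
        c = tidy([("a1", "g1", "T0", 800), ("a2", "g1", "T0", 1000),
                  ("b1", "g2", "T0", 900), ("b2", "g2", "T0", 920)])
        s = summarize(c).set_index("group")
        assert s.loc["pooled", "mean"] == pytest.approx(
            (s.loc["g1", "mean"] + s.loc["g2", "mean"]) / 2
        )

    def test_identical_counts_sd_zero(self):
        c = tidy([("s1", "g", "T0", 5), ("s2", "g", "T0", 5)])
        assert summarize(c)["sd"].iloc[0] == 0.0

    def test_single_subject_sd_missing(self):
        c = tidy([("s1", "g", "T0", 5)])
        assert np.isnan(summarize(c)["sd"].iloc[0])

    def test_unbalanced_design_rejected(self):
        c = tidy([("s1", "g", "T0", 5), ("s1", "g", "T1", 6), ("s2", "g", "T0", 7)])
        with pytest.raises(ValueError):
            summarize(c)

    def test_noise_free_simulation_reproduces_scaled_means(self):
        """With all noise at zero, summarize o simulate reproduces
        round(mu_g * (1 + delta_gt)) exactly."""
        params = CohortParams(
            n_per_group=3,
            baseline_sd={g: 0.0 for g in study.GROUPS},
            sigma={g: {t: 0.0 for t in study.POST_BASELINE} for g in study.GROUPS},
            seed=0,
        )
        cohort, _ = simulate_cohort(params)
        s = summarize(cohort).set_index(["group", "timepoint"])
        for g in study.GROUPS:
            mu = study.BASELINE_MEAN[g]
            for t in study.TIMEPOINTS:
                d = 0.0 if t == "T0" else study.DELTA[g][t]
                assert s.loc[(g, t), "mean"] == np.round(mu * (1 + d))


class TestRmAnova:
    def test_matches_frozen_splitplot_oracle(self, toy_splitplot):
        """SS/df/F/p agree with the independently computed decomposition of
        the printed toy table."""
        res = rm_anova(toy_splitplot).table.set_index("effect")
        assert res.loc["group", "ss"] == pytest.approx(96.333333, abs=1e-5)
        assert res.loc["subject(group)", "ss"] == pytest.approx(11.666667, abs=1e-5)
        assert res.loc["time", "ss"] == pytest.approx(48.0, abs=1e-6)
        assert res.loc["group:time", "ss"] == pytest.approx(1.333333, abs=1e-5)
        assert res.loc["residual", "ss"] == pytest.approx(1.666667, abs=1e-5)
        assert res.loc["group", "F"] == pytest.approx(33.028571, abs=1e-4)
        assert res.loc["time", "F"] == pytest.approx(115.2, abs=1e-3)
        assert res.loc["group:time", "F"] == pytest.approx(3.2, abs=1e-4)
        assert res.loc["group", "p"] == pytest.approx(0.004544, abs=1e-5)
        assert res.loc["group:time", "p"] == pytest.approx(0.148148, abs=1e-5)
        assert list(res["df"]) == [1, 4, 1, 1, 4]

    def test_matches_pingouin_on_simulated_cohort(self):
        pg = pytest.importorskip("pingouin")
        cohort, _ = simulate_cohort(CohortParams(seed=13))
        mine = rm_anova(cohort).table.set_index("effect")
        ref = pg.mixed_anova(data=cohort, dv="count", within="timepoint",
                             subject="subject", between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["timepoint", "F"])
        assert mine.loc["group:time", "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert mine.loc["group:time", "p"] == pytest.approx(ref.loc["Interaction", "p_unc"])

    def test_ss_identity(self):
        """SS_total decomposes exactly into the five strata."""
        for seed in range(10):
            cohort, _ = simulate_cohort(CohortParams(seed=seed))
            t = rm_anova(cohort).table
            y = cohort.pivot(index="subject", columns="timepoint", values="count").to_numpy(float)
            ss_total = ((y - y.mean()) ** 2).sum()
            assert t["ss"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_identical_group_trajectories_zero_interaction(self):
        traj = {"t1": 100.0, "t2": 80.0, "t3": 90.0}
        rows = []
        for g, eps in (("g1", 3.0), ("g2", 5.0)):
            for sub, sign in ((f"{g}a", 1.0), (f"{g}b", -1.0)):
                for t, base in traj.items():
                    # constant per-subject offset + zero-mean within-subject
                    # wiggle: cell means stay equal across groups
                    rows.append((sub, g, t,
                                 base + 2.0 * sign + sign * eps * {"t1": 1, "t2": -1, "t3": 0}[t]))
        res = rm_anova(tidy(rows)).table.set_index("effect")
        assert res.loc["group:time", "ss"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["group:time", "p"] == pytest.approx(1.0)
        assert res.loc["residual", "ss"] > 0

    def test_degenerate_zero_residual_raises(self):
        rows = [(s, g, t, 100) for g in ("g1", "g2") for s in (f"{g}a", f"{g}b") for t in ("t1", "t2")]
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova(tidy(rows))

    def test_interaction_power_under_study_conditions(self):
        """Default two-group cohorts give interaction p < 0.001 in the median
        replicate (the study's headline significance)."""
        ps = [rm_anova(simulate_cohort(CohortParams(seed=50_000 + s))[0]).p("group:time")
              for s in range(100)]
        assert np.median(ps) < 0.001


class TestOneWayTimeAnova:
    def test_two_timepoints_f_equals_paired_t_squared(self, toy_splitplot):
        from scipy import stats as sps

        res = one_way_time_anova(toy_splitplot).table.set_index("effect")
        wide = toy_splitplot.pivot(index="subject", columns="timepoint", values="count")
        t = sps.ttest_rel(wide["t1"], wide["t2"])
        assert res.loc["time", "F"] == pytest.approx(t.statistic**2)
        assert res.loc["time", "p"] == pytest.approx(t.pvalue)

    def test_null_type_one_error_calibrated(self):
        """No time effect: rejection rate of the time test is about 5% over
        500 simulated null cohorts (homoscedastic per-timepoint noise)."""
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            base = rng.normal(900, 150, size=8)
            y = base[:, None] * (1 + rng.normal(0, 0.1, size=(8, 4)))
            rows = [(f"s{i}", "g", f"t{t}", y[i, t]) for i in range(8) for t in range(4)]
            p = one_way_time_anova(tidy(rows)).table.set_index("effect").loc["time", "p"]
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.075

    def test_power_in_affected_group(self):
        """Restricted to the light-exposed group, the time effect is
        significant in at least 95% of replicate cohorts."""
        sig = 0
        for s in range(100):
            cohort, _ = simulate_cohort(CohortParams(seed=60_000 + s))
            g1 = cohort[cohort["group"] == "group1"]
            p = one_way_time_anova(g1).table.set_index("effect").loc["time", "p"]
            sig += p < 0.05
        assert sig >= 95


class TestPairedWilcoxon:
    def test_identical_vectors_p_one(self):
        stat, p = paired_wilcoxon([3, 4, 5], [3, 4, 5])
        assert p == 1.0

    def test_extreme_shift_minimal_exact_p(self):
        a = np.arange(10, dtype=float)
        stat, p = paired_wilcoxon(a + 100.0, a)
        assert p == pytest.approx(2 / 2**10)

    def test_exact_p_matches_full_enumeration(self):
        """n = 6 with ties and a zero: exact p equals the explicit loop over
        all 2^6 sign assignments (Pratt zero handling, average ranks)."""
        from scipy.stats import rankdata

        a = np.array([10.0, 12.0, 9.0, 15.0, 8.0, 11.0])
        b = np.array([12.0, 12.0, 12.0, 12.0, 12.0, 12.0])
        d = a - b
        ranks = rankdata(np.abs(d))
        nz = np.nonzero(d)[0]
        obs = ranks[nz][d[nz] > 0].sum()
        total = ranks[nz].sum()
        mean = total / 2
        hits = 0
        for signs in product([1, -1], repeat=len(nz)):
            w = sum(r for r, s in zip(ranks[nz], signs) if s > 0)
            if abs(w - mean) >= abs(obs - mean) - 1e-9:
                hits += 1
        expected_p = hits / 2 ** len(nz)
        _, p = paired_wilcoxon(a, b)
        assert p == pytest.approx(expected_p)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_without_ties(self, seed):
        from scipy import stats as sps

        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = a + rng.normal(0.4, 1.0, size=12)
        while len(np.unique(np.abs(a - b))) < 12 or np.any(a == b):
            b = a + rng.normal(0.4, 1.0, size=12)
        stat, p = paired_wilcoxon(a, b)
        ref = sps.wilcoxon(a, b, method="exact")
        assert p == pytest.approx(ref.pvalue)
        assert stat == pytest.approx(ref.statistic)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = a + rng.normal(0.2, 1.0, size=40)
        from scipy import stats as sps

        _, p = paired_wilcoxon(a, b)
        ref = sps.wilcoxon(a, b, zero_method="pratt", correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue)

    def test_published_scan_orientation_comparison_shape(self):
        # six eyes, horizontal vs vertical scans: statistic defined, p in (0, 1]
        h = [950.0, 900.0, 1020.0, 980.0, 890.0, 990.0]
        v = [962.0, 915.0, 1005.0, 991.0, 902.0, 997.0]
        stat, p = paired_wilcoxon(h, v)
        assert 0 < p <= 1


class TestNormalityCheck:
    def test_type_one_error_calibration(self):
        """Normal draws: Shapiro-Wilk rejects at about the nominal 5% rate."""
        rng = np.random.default_rng(2)
        rej = sum(normality_check(rng.normal(size=200))[2] for _ in range(500))
        assert 0.03 <= rej / 500 <= 0.075

    def test_power_against_skew(self):
        rng = np.random.default_rng(3)
        rej = sum(normality_check(rng.exponential(size=50))[2] for _ in range(200))
        assert rej / 200 > 0.9

    def test_minimal_n_finite_w(self):
        w, p, _ = normality_check([1.0, 2.0, 4.0])
        assert 0 < w <= 1

    def test_constant_input_undefined(self):
        w, p, flag = normality_check([5.0, 5.0, 5.0])
        assert np.isnan(w) and not flag

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


class TestSubgroupMedians:
    def test_three_value_subgroup(self):
        c = tidy([("s1", "g", "T0", 859), ("s2", "g", "T0", 876), ("s3", "g", "T0", 892)])
        out = subgroup_medians(c, {"s1": "dark", "s2": "dark", "s3": "dark"})
        assert out["median"].iloc[0] == 876
        assert 859 <= out["q25"].iloc[0] <= 892
        assert 859 <= out["q75"].iloc[0] <= 892

    def test_single_subject_degenerate_iqr(self):
        c = tidy([("s1", "g", "T0", 700)])
        out = subgroup_medians(c, {"s1": "light"})
        assert out["median"].iloc[0] == 700
        assert out["q25"].iloc[0] == out["q75"].iloc[0] == 700

    def test_all_equal_zero_width_iqr(self):
        c = tidy([(f"s{i}", "g", "T0", 500) for i in range(4)])
        out = subgroup_medians(c, {f"s{i}": "x" for i in range(4)})
        assert out["q75"].iloc[0] - out["q25"].iloc[0] == 0.0

    def test_unlabelled_subject_rejected(self):
        c = tidy([("s1", "g", "T0", 1), ("s2", "g", "T0", 2)])
        with pytest.raises(ValueError):
            subgroup_medians(c, {"s1": "x"})
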