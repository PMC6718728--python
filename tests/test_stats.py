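import itertools
import math

import numpy as np
import pandas as pd
import pytest

from myoracle import (
    PowerQuery,
    TaskTimeline,
    Zone,
    anova_ber,
    cohens_f_from_ss,
    compare_groups,
    posthoc_power,
    required_sample_size,
    trend_with_cooks,
    zone_failure_summary,
)
from myoracle.stats import StatsError
from .conftest import make_session, spurious_close


def cooks_loo_oracle(x, y):
    """Cook's distance by leave-one-out refits of the straight-line fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    p = 2
    s2 = resid @ resid / (len(x) - p)
    out = []
    for i in range(len(x)):
        keep = np.arange(len(x)) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        diff = X @ beta - X @ beta_i
        out.append(diff @ diff / (p * s2))
    return np.array(out)


def balanced_ber_table(n_subjects=6, shift=0.0, noise_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for ft in ("tc", "sc", "tcsc"):
            for w in (0.5, 1.0, 3.0):
                for ov in ("none", "half"):
                    val = 20.0 + rng.normal(0.0, noise_sd)
                    if ft == "tc":
                        val += shift
                    rows.append(
                        {
                            "subject": f"S{s}",
                            "feature_type": ft,
                            "window": w,
                            "overlap": ov,
                            "ber": val,
                        }
                    )
    return pd.DataFrame(rows)


class TestZoneSummary:
    def make_tasked_session(self, failure_times):
        tasks = [
            TaskTimeline(20.0 * k, 20.0 * k + 5, 20.0 * k + 10, 20.0 * k + 18)
            for k in range(5)
        ]
        return make_session(
            tasks, failures=[spurious_close(t) for t in failure_times]
        )

    def test_failures_only_in_post_grasp(self):
        session = self.make_tasked_session([20.0 * k + 15 for k in range(5)])
        summary = zone_failure_summary({"A": [session]})
        s = summary.per_subject["A"]
        assert s.mean_by_zone[Zone.PRE_GRASP] == 0.0
        assert s.mean_by_zone[Zone.GRASP] == 0.0
        assert s.mean_by_zone[Zone.POST_GRASP] == 1.0

    def test_one_failure_per_task_at_grasp_midpoint(self):
        session = self.make_tasked_session([20.0 * k + 7.5 for k in range(5)])
        s = zone_failure_summary({"A": [session]}).per_subject["A"]
        assert s.mean_by_zone[Zone.GRASP] == 1.0
        assert s.sd_by_zone[Zone.GRASP] == 0.0
        # midpoint of a 10-bin histogram
        grasp_hist = s.hist[1]
        assert grasp_hist[5] == 1.0
        assert grasp_hist.sum() == 1.0

    def test_zone_means_sum_to_overall_mean(self, default_session):
        s = zone_failure_summary({"A": [default_session]}).per_subject["A"]
        assert sum(s.mean_by_zone.values()) == pytest.approx(s.mean_overall)

    def test_uniform_failures_fill_bins_flatly(self):
        rng = np.random.default_rng(0)
        tasks = [TaskTimeline(20.0 * k, 20.0 * k + 5, 20.0 * k + 10, 20.0 * k + 18) for k in range(200)]
        times = [20.0 * k + 10.0 + 8.0 * rng.uniform() * 0.999 for k in range(200)]
        session = make_session(tasks, [spurious_close(t) for t in times])
        s = zone_failure_summary({"A": [session]}).per_subject["A"]
        counts = s.hist[2] * 200  # back to raw counts
        n, b = 200, 10
        band = 3.0 * math.sqrt(n * (1 / b) * (1 - 1 / b))
        assert counts.sum() == n
        for c in counts:
            assert abs(c - n / b) < band


class TestTrendWithCooks:
    def test_collinear_points_have_zero_distances(self):
        d = trend_with_cooks([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert d.slope == pytest.approx(2.0)
        assert d.intercept == pytest.approx(1.0)
        assert np.allclose(d.residuals, 0.0, atol=1e-12)
        assert np.allclose(d.cooks_d, 0.0, atol=1e-12)

    def test_matches_leave_one_out_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.uniform(0, 10, size=12)
            y = 2.0 * x + rng.normal(0, 1.5, size=12)
            d = trend_with_cooks(x, y)
            assert np.allclose(d.cooks_d, cooks_loo_oracle(x, y), atol=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(StatsError):
            trend_with_cooks([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(StatsError):
            trend_with_cooks([0.0, 1.0], [0.0, 1.0])


class TestCompareGroups:
    def test_identical_groups_not_distinguishable(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(g, g)
        assert res.wilcoxon_p > 0.9

    def test_fully_separated_small_groups_exact_p(self):
        res = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        # minimal possible rank-sum W = 1+2+3 = 6; exhaustive permutation
        # oracle: 2 / C(6,3) = 0.1 two-sided
        assert res.wilcoxon_w == 6.0
        assert res.wilcoxon_p == pytest.approx(0.1)

    def test_exhaustive_permutation_oracle_small_case(self):
        a = [3.0, 7.0, 9.0]
        b = [1.0, 4.0, 12.0, 15.0]
        res = compare_groups(a, b)
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        w_obs = sum(ranks[v] for v in a)
        n = len(pooled)
        ws = [
            sum(c)
            for c in itertools.combinations(range(1, n + 1), len(a))
        ]
        mean_w = np.mean(ws)
        p = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in ws) / len(ws)
        assert res.wilcoxon_w == w_obs
        assert res.wilcoxon_p == pytest.approx(p)

    def test_shapiro_detects_gaussian_as_plausible(self):
        rng = np.random.default_rng(2)
        res = compare_groups(rng.normal(size=50), rng.normal(size=50))
        assert res.shapiro_p_a > 0.001

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_constant_response_gives_zero_f(self):
        table = balanced_ber_table(noise_sd=0.0)
        table["ber"] = 20.0
        rep = anova_ber(table)
        for f_val, *_ in rep.effects.values():
            assert f_val == 0.0
        assert rep.oneway_f == 0.0

    def test_three_way_degrees_of_freedom_at_108(self):
        rep = anova_ber(balanced_ber_table(n_subjects=6, seed=1))
        assert rep.effects["feature_type"][1:3] == (2, 90)
        assert rep.effects["window"][1:3] == (2, 90)
        assert rep.effects["overlap"][1:3] == (1, 90)
        assert rep.oneway_df == (2, 105)

    def test_constructed_feature_type_effect_is_recovered(self):
        rep = anova_ber(balanced_ber_table(shift=10.0, noise_sd=1.0, seed=2))
        assert rep.effects["feature_type"][3] < 0.001
        tukey = rep.tukey
        involving_tc = tukey[
            (tukey["group1"] == "tc") | (tukey["group2"] == "tc")
        ]
        other = tukey[
            (tukey["group1"] != "tc") & (tukey["group2"] != "tc")
        ]
        assert involving_tc["reject"].all()
        assert not other["reject"].any()

    def test_ss_decomposition_sums_to_total(self):
        table = balanced_ber_table(shift=4.0, seed=3)
        rep = anova_ber(table)
        total = float(((table["ber"] - table["ber"].mean()) ** 2).sum())
        assert sum(rep.ss.values()) == pytest.approx(total)

    def test_unbalanced_table_rejected(self):
        table = balanced_ber_table().iloc[:-1]
        with pytest.raises(StatsError):
            anova_ber(table)


class TestPower:
    def test_cohens_f_from_ss(self):
        assert cohens_f_from_ss(4.0, 4.0) == 1.0
        assert cohens_f_from_ss(0.0, 4.0) == 0.0
        assert cohens_f_from_ss(1.0, 4.0) == 0.5

    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.001, 0.01, 0.05, 0.2):
            for df_num, groups in ((1, 18), (2, 3), (5, 10)):
                q = PowerQuery(
                    f=0.0, alpha=alpha, n_total=108, df_num=df_num, n_groups=groups
                )
                assert posthoc_power(q).power == pytest.approx(alpha, abs=1e-9)

    def test_power_increases_with_effect_size_and_n(self):
        base = posthoc_power(
            PowerQuery(f=0.3, alpha=0.05, n_total=60, df_num=2, n_groups=3)
        ).power
        bigger_f = posthoc_power(
            PowerQuery(f=0.5, alpha=0.05, n_total=60, df_num=2, n_groups=3)
        ).power
        bigger_n = posthoc_power(
            PowerQuery(f=0.3, alpha=0.05, n_total=120, df_num=2, n_groups=3)
        ).power
        assert bigger_f > base
        assert bigger_n > base

    def test_noncentrality_and_df_convention(self):
        res = posthoc_power(
            PowerQuery(f=0.5, alpha=0.05, n_total=108, df_num=2, n_groups=18)
        )
        assert res.noncentrality == pytest.approx(0.25 * 108)
        assert res.df_den == 90

    def test_required_n_is_left_inverse_of_power(self):
        f, alpha, df_num, groups = 0.25, 0.05, 2, 18
        n = required_sample_size(f, alpha, df_num, groups, 0.8)
        at_n = posthoc_power(
            PowerQuery(f=f, alpha=alpha, n_total=n, df_num=df_num, n_groups=groups)
        ).power
        below = posthoc_power(
            PowerQuery(f=f, alpha=alpha, n_total=n - 1, df_num=df_num, n_groups=groups)
        ).power
        assert at_n >= 0.8 > below

    def test_huge_effect_hits_search_floor(self):
        groups, df_num = 18, 1
        n = required_sample_size(10.0, 0.05, df_num, groups, 0.8)
        assert n == groups + df_num + 1

    def test_zero_effect_unattainable(self):
        with pytest.raises(StatsError):
            required_sample_size(0.0, 0.05, 1, 18, 0.8)
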