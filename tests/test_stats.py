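"""Group-level statistics: t-tests, rm-ANOVA, Tukey HSD, Wilcoxon, d'."""

import numpy as np
import pytest
from scipy import stats as sps

from surfdecode.stats import (
    dprime,
    one_sample_t_one_tailed,
    rm_anova_two_way,
    tukey_hsd,
    tukey_on_factor,
    wilcoxon_signed_rank,
)


class TestOneSampleT:
    def test_hand_formula_oracle(self):
        res = one_sample_t_one_tailed(np.array([0.6, 0.7, 0.8]), 0.5)
        assert res.t == pytest.approx(3.4641016, abs=1e-6)
        assert res.dof == 2

    def test_values_at_baseline_give_t_zero(self):
        res = one_sample_t_one_tailed(np.array([0.5, 0.5, 0.5]), 0.5)
        assert res.t == 0.0 and res.p_one_tailed == 0.5

    def test_zero_variance_above_baseline(self):
        res = one_sample_t_one_tailed(np.array([0.7, 0.7]), 0.5)
        assert np.isinf(res.t) and res.p_one_tailed == 0.0

    def test_bonferroni_significance_arithmetic(self):
        vals = np.array([0.6, 0.7, 0.8])
        strong = one_sample_t_one_tailed(vals, 0.5, m_tests=1)
        # p ~ 0.037: significant against 0.05 but not against 0.05/10
        assert strong.significant
        weak = one_sample_t_one_tailed(vals, 0.5, m_tests=10)
        assert weak.alpha_corrected == pytest.approx(0.005)
        assert not weak.significant

    def test_type_one_rate_calibrated_at_null(self):
        """At the null, the one-tailed test rejects ~5% of the time."""
        rng = np.random.default_rng(6)
        rejections = sum(
            one_sample_t_one_tailed(0.5 + 0.02 * rng.standard_normal(16),
                                    0.5).significant
            for _ in range(2000)
        )
        rate = rejections / 2000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)


def _anova_oracle(d):
    """Brute-force sums-of-squares decomposition with explicit loops."""
    n, a, b = d.shape
    g = d.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "ABS")}
    for i in range(a):
        ss["A"] += n * b * (d[:, i, :].mean() - g) ** 2
    for j in range(b):
        ss["B"] += n * a * (d[:, :, j].mean() - g) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                d[:, i, j].mean() - d[:, i, :].mean() - d[:, :, j].mean() + g
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (
                d[s, i, :].mean() - d[s].mean() - d[:, i, :].mean() + g
            ) ** 2
        for j in range(b):
            ss["BS"] += a * (
                d[s, :, j].mean() - d[s].mean() - d[:, :, j].mean() + g
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (
                    d[s, i, j] - d[s, i, :].mean() - d[s, :, j].mean()
                    - d[:, i, j].mean() + d[s].mean() + d[:, i, :].mean()
                    + d[:, :, j].mean() - g
                ) ** 2
    F_A = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    F_B = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    F_AB = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABS"] / ((a - 1) * (b - 1) * (n - 1))
    )
    return F_A, F_B, F_AB


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        d = np.full((4, 2, 3), 5.0)
        tab = rm_anova_two_way(d)
        assert all(tab.effects[k].F == 0.0 for k in ("A", "B", "AxB"))

    def test_2x2_toy_matches_ss_oracle(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=(3, 2, 2))
        tab = rm_anova_two_way(d)
        fa, fb, fab = _anova_oracle(d)
        assert tab.effects["A"].F == pytest.approx(fa, abs=1e-8)
        assert tab.effects["B"].F == pytest.approx(fb, abs=1e-8)
        assert tab.effects["AxB"].F == pytest.approx(fab, abs=1e-8)

    def test_study_sized_design_matches_oracle_and_dofs(self):
        """3 contrasts x 10 ROIs x 16 subjects: F and dof pairs match
        the loop oracle and the expected (2,30)/(9,135)/(18,270)."""
        rng = np.random.default_rng(8)
        d = rng.normal(size=(16, 3, 10)) + 0.3 * rng.normal(size=(16, 1, 1))
        tab = rm_anova_two_way(d, design_label="3x10")
        fa, fb, fab = _anova_oracle(d)
        assert tab.effects["A"].F == pytest.approx(fa, rel=1e-9)
        assert tab.effects["B"].F == pytest.approx(fb, rel=1e-9)
        assert tab.effects["AxB"].F == pytest.approx(fab, rel=1e-9)
        assert (tab.effects["A"].df, tab.effects["A"].error_df) == (2, 30)
        assert (tab.effects["B"].df, tab.effects["B"].error_df) == (9, 135)
        assert (tab.effects["AxB"].df, tab.effects["AxB"].error_df) == (18, 270)

    def test_matches_pingouin_cross_check(self):
        """Independent implementation check against pingouin's two-way
        repeated-measures ANOVA."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        d = rng.normal(size=(6, 2, 4))
        rows = [
            {"subj": s, "A": i, "B": j, "y": d[s, i, j]}
            for s in range(6) for i in range(2) for j in range(4)
        ]
        ref = pg.rm_anova(data=pd.DataFrame(rows), dv="y",
                          within=["A", "B"], subject="subj")
        tab = rm_anova_two_way(d)
        for src, key in [("A", "A"), ("B", "B"), ("A * B", "AxB")]:
            f_ref = float(ref.loc[ref["Source"] == src, "F"].iloc[0])
            assert tab.effects[key].F == pytest.approx(f_ref, rel=1e-6)

    def test_per_subject_offsets_leave_f_unchanged(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(5, 2, 3))
        offset = rng.normal(size=(5, 1, 1)) * 50
        t1, t2 = rm_anova_two_way(d), rm_anova_two_way(d + offset)
        for k in ("A", "B", "AxB"):
            assert t1.effects[k].F == pytest.approx(t2.effects[k].F, rel=1e-9)

    def test_incomplete_design_rejected(self):
        d = np.ones((3, 2, 2))
        d[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_two_way(d)


class TestTukey:
    def test_identical_means_not_significant(self):
        m = np.tile([1.0, 1.0, 1.0], (5, 1)) + \
            np.random.default_rng(0).normal(scale=1e-9, size=(5, 3))
        res = tukey_hsd(m, error_ms=1.0, error_df=8)
        assert all(not r.significant for r in res)

    def test_two_levels_q_equals_sqrt2_paired_t(self):
        """Algebraic identity: with two within-subject levels,
        q = sqrt(2)*|paired t|."""
        rng = np.random.default_rng(5)
        d = rng.normal(size=(8, 2, 4))  # subjects x A(2) x B(4)
        tab = rm_anova_two_way(d)
        res = tukey_on_factor(d, tab, factor="A")
        marg = d.mean(axis=2)
        t, _ = sps.ttest_rel(marg[:, 0], marg[:, 1])
        assert res[0].q == pytest.approx(np.sqrt(2) * abs(t), rel=1e-9)

    def test_single_level_returns_empty(self):
        assert tukey_hsd(np.ones((4, 1)), 1.0, 3) == []

    def test_type_one_rate_matches_studentized_range(self):
        """Null simulation: the frequency of any significant pair at
        alpha=.05 matches the studentized-range calibration."""
        rng = np.random.default_rng(9)
        hits = 0
        n_sim = 1500
        for _ in range(n_sim):
            d = rng.normal(size=(6, 3, 2)) + 2.0 * rng.normal(size=(6, 1, 1))
            tab = rm_anova_two_way(d)
            res = tukey_on_factor(d, tab, factor="A")
            hits += any(r.significant for r in res)
        rate = hits / n_sim
        assert abs(rate - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / n_sim)


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(x, x)

    def test_seven_positive_differences_exact_p(self):
        """n=7, all differences one-signed: exact two-tailed
        p = 2/2^7 = 0.015625."""
        x = np.array([3.0, 4, 5, 6, 7, 8, 9])
        y = x - np.array([0.5, 1.0, 1.5, 0.7, 0.9, 1.1, 1.3])
        z, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(0.015625, abs=1e-12)
        assert z > 0

    def test_sign_flip_negates_z_keeps_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = x - rng.exponential(size=10) * rng.choice([-1, 1], 10)
        z1, p1 = wilcoxon_signed_rank(x, y)
        z2, p2 = wilcoxon_signed_rank(y, x)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_exact_path_matches_scipy(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            _, p = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-10)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=30)
        y = x - 0.4 - rng.normal(size=30)
        _, p = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.01)


class TestDprime:
    def test_equal_rates_give_zero(self):
        res = dprime(42, 58, 42, 58)
        assert res.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_rates_match_quantile_oracle(self):
        """hit .84 / fa .16: d' = 2*Phi^-1(.84) ~= 1.989."""
        res = dprime(84, 16, 16, 84)
        assert res.d_prime == pytest.approx(2 * sps.norm.ppf(0.84), abs=1e-9)
        assert res.d_prime == pytest.approx(1.989, abs=0.001)

    def test_perfect_hit_rate_triggers_correction(self):
        res = dprime(50, 0, 10, 40)
        assert res.correction_applied and np.isfinite(res.d_prime)

    def test_empty_cells_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 5, 5)
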