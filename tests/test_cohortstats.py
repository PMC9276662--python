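import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import vesselfrac as vf
from vesselfrac.cohortstats import (
    compare_groups,
    fisher_exact,
    icc_absolute_agreement,
    rank_outlier_index,
    shapiro_wilk,
    spearman,
    welch_t,
)


class TestWelch:
    def test_published_group_summaries(self):
        # group summaries: (n, mean, sd) for the low-burden vs no-burden groups
        res = welch_t((8, 1.5172, 0.0248), (14, 1.5653, 0.0304))
        assert res.t_stat == pytest.approx(4.018, rel=0.02)
        assert res.df == pytest.approx(17.28, rel=0.02)
        assert res.mean_diff == pytest.approx(0.0481, abs=1e-4)
        assert res.ci95_low == pytest.approx(0.0229, abs=5e-4)
        assert res.ci95_high == pytest.approx(0.0733, abs=5e-4)
        assert res.p_two_sided < 0.005

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x)
        assert res.t_stat == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_extended_precision_closed_form(self):
        import sympy

        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0.5, 2, 20)
            res = welch_t(a, b)
            # independent oracle: exact rational arithmetic on the closed form
            ra = [sympy.Rational(x) for x in a.tolist()]
            rb = [sympy.Rational(x) for x in b.tolist()]
            na, nb = len(ra), len(rb)
            ma, mb = sum(ra) / na, sum(rb) / nb
            va = sum((x - ma) ** 2 for x in ra) / (na - 1) / na
            vb = sum((x - mb) ** 2 for x in rb) / (nb - 1) / nb
            t_exact = (mb - ma) / sympy.sqrt(va + vb)
            df_exact = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            assert abs(res.t_stat - float(t_exact)) < 1e-10
            assert abs(res.df - float(df_exact)) < 1e-10

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1.7, 11)
        res = welch_t(a, b)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert res.t_stat == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 12)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)
        assert r1.ci95_low == pytest.approx(-r2.ci95_high)
        assert r1.ci95_high == pytest.approx(-r2.ci95_low)

    def test_pooled_variance_option(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        res = welch_t(a, b, equal_var=True)
        ref = sps.ttest_ind(b, a, equal_var=True)
        assert res.t_stat == pytest.approx(ref.statistic, abs=1e-12)
        assert res.df == 20

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="undefined"):
            welch_t((5, 1.0, 0.0), (5, 1.0, 0.0))


def naive_midrank(x):
    """Brute-force mid-ranks, independent of scipy.rankdata."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        out[i] = less + (equal + 1) / 2.0
    return out


class TestSpearman:
    def test_perfect_inverse_monotone(self):
        x = np.arange(1, 11, dtype=float)
        res = spearman(x, -(x**3))
        assert res.rho == pytest.approx(-1.0)

    def test_worked_small_example(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)

    def test_matches_pearson_on_midranks_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            if rng.random() < 0.3:  # inject ties
                x = np.round(x)
            rho = spearman(x, y).rho
            rx, ry = naive_midrank(x), naive_midrank(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        assert res.p_method == "exact-permutation"
        # independent oracle: loop over all 720 permutations with scipy
        rho_obs = sps.spearmanr(x, y).statistic
        hits = total = 0
        for perm in itertools.permutations(y):
            r = sps.spearmanr(x, perm).statistic
            hits += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        assert res.p_two_sided == pytest.approx(hits / total, abs=1e-12)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=22), rng.normal(size=22)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.1, 5, 30)
        y = rng.uniform(0.1, 5, 30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3).rho == pytest.approx(base)
        assert spearman(np.log(x), -1.0 / y).rho == pytest.approx(base)

    def test_cohort_coupling_sign_recovery(self):
        # negative coupling at the study's n=22 yields a negative rho in
        # nearly every replicate
        neg = 0
        for seed in range(200):
            c = vf.make_cohort(vf.CohortSpec(seed=seed))
            neg += spearman(c.qrisk2, c.df_mean).rho < 0
        assert neg >= 190

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError, match="rank"):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


def hypergeom_table_p(table):
    """Brute-force two-sided Fisher p: enumerate all tables with the
    observed margins and sum probabilities <= the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (math.comb(r1, aa) * math.comb(r2, c1 - aa)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_sex_proportion_table_not_significant(self):
        res = fisher_exact([[2, 6], [5, 9]])
        assert res.p_two_sided > 0.05

    def test_empty_column_gives_p_one(self):
        assert fisher_exact([[0, 7], [0, 9]]).p_two_sided == pytest.approx(1.0)

    def test_matches_enumeration_all_small_tables(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        table = [[a, b], [c, d]]
                        ours = fisher_exact(table).p_two_sided
                        assert ours == pytest.approx(
                            hypergeom_table_p(table), abs=1e-9), table

    def test_errors(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestICC:
    def test_identical_raters_give_exactly_one(self):
        x = np.linspace(1.4, 1.7, 12)
        res = icc_absolute_agreement(np.column_stack([x, x]))
        assert res.icc == 1.0
        assert res.ci95_low == res.ci95_high == 1.0

    def test_dominant_noise_destroys_agreement(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            subj = rng.normal(1.55, 0.03, 50)
            ratings = np.column_stack([subj, subj + rng.normal(0, 0.5, 50)])
            assert icc_absolute_agreement(ratings).icc < 0.2

    def test_worked_anova_table(self):
        # independent oracle: explicit sum-of-squares arithmetic on a 6x2 matrix
        m = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 6], [10, 9]], float)
        n, k = m.shape
        grand = m.mean()
        msr = k * np.sum((m.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((m.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (np.sum((m - grand) ** 2)
               - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        res = icc_absolute_agreement(m)
        assert res.icc == pytest.approx(expected, abs=1e-12)
        assert res.ci95_low <= res.icc <= res.ci95_high

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        c = vf.make_cohort(vf.CohortSpec(seed=2))
        m = c[["df_rater1", "df_rater2"]].to_numpy()
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(len(m)), 2),
            "rater": np.tile([1, 2], len(m)),
            "y": m.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subj", raters="rater",
                                 ratings="y")
        ref_row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        res = icc_absolute_agreement(m)
        assert res.icc == pytest.approx(ref_row.ICC, abs=1e-9)
        lo, hi = ref_row.CI95
        assert res.ci95_low == pytest.approx(lo, abs=5e-3)
        assert res.ci95_high == pytest.approx(hi, abs=5e-3)

    def test_errors(self):
        with pytest.raises(ValueError, match="5 subjects"):
            icc_absolute_agreement(np.ones((3, 2)))
        with pytest.raises(ValueError, match="missing"):
            m = np.random.default_rng(0).random((6, 2))
            m[0, 0] = np.nan
            icc_absolute_agreement(m)
        with pytest.raises(ValueError, match="variance"):
            icc_absolute_agreement(np.ones((6, 2)))


class TestShapiro:
    def test_normal_scores_best_case(self):
        n = 50
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        w, _ = shapiro_wilk(x)
        assert w > 0.99

    def test_lognormal_rejected(self):
        rejections = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).normal(0, 1.0, 100))
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 95

    def test_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestCompareGroups:
    def test_full_report_on_default_cohort(self):
        c = vf.make_cohort(vf.CohortSpec(seed=1))
        report = compare_groups(c)
        assert report["n_pos"] == 8 and report["n_neg"] == 14
        assert set(report["descriptives"]) == {"age", "bmi", "sbp", "tchdl",
                                               "qrisk2", "df_mean"}
        # dimension lower in the lesion group by construction
        w = report["df_welch"]
        assert w["mean_diff"] > 0
        assert report["interrater_icc"]["icc"] > 0.9
        assert report["qrisk_spearman"]["rho"] < 0
        assert "excluded_subject" in report["qrisk_spearman_no_outlier"]
        assert 0 <= report["sex_fisher"]["p_two_sided"] <= 1

    def test_outlier_rule_is_deterministic_argmax(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        x[7] = 100.0  # extreme rank-space point
        assert rank_outlier_index(x, y) == 7

    def test_single_subject_group_errors(self):
        c = vf.make_cohort(vf.CohortSpec(seed=1))
        c = c[c.group.eq("WMH_neg") | (c.subject_id == "S0001")]
        with pytest.raises(ValueError, match="2 subjects"):
            compare_groups(c)

    def test_stats_identical_for_same_df_values(self):
        c = vf.make_cohort(vf.CohortSpec(seed=4))
        r1 = compare_groups(c)
        r2 = compare_groups(c.copy())
        assert r1 == r2
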