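"""Cohort-level statistics for two-group fractal-dimension studies.

The layer reproduces a standard clinical comparison sequence:
group descriptives, Fisher's exact test on sex proportion, Welch's
unequal-variance t-test on the averaged dimension, Spearman rank
correlation between the cardiovascular risk score and the dimension,
a two-way mixed absolute-agreement intraclass correlation for
inter-rater reliability, and Shapiro-Wilk normality checks that route
the analysis (t-test for normal dimension values, rank correlation for
the skewed risk score).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "SpearmanResult",
    "ICCResult",
    "FisherResult",
    "welch_t",
    "spearman",
    "icc_absolute_agreement",
    "fisher_exact",
    "shapiro_wilk",
    "rank_outlier_index",
    "compare_groups",
]


@dataclass
class WelchResult:
    t_stat: float
    df: float
    p_two_sided: float
    mean_diff: float
    ci95_low: float
    ci95_high: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpearmanResult:
    rho: float
    p_two_sided: float
    n: int
    p_method: str  # "exact-permutation" or "t-approximation"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ICCResult:
    icc: float
    ci95_low: float
    ci95_high: float
    model: str = "two-way mixed, absolute agreement, single measurement"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FisherResult:
    p_two_sided: float
    table: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {"p_two_sided": self.p_two_sided,
                "table": [list(r) for r in self.table]}


def _summarize(sample) -> tuple[int, float, float]:
    """Accept raw values (list/array) or an (n, mean, sd) summary.

    Only a *tuple* of length 3 is read as a summary, so a 3-element list
    or array is unambiguously raw data.
    """
    if isinstance(sample, tuple) and len(sample) == 3:
        n, m, s = sample
        return int(n), float(m), float(s)
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1D raw values or an (n, mean, sd) triple")
    return len(x), float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0


def welch_t(group_a, group_b, equal_var: bool = False) -> WelchResult:
    """Two-sample t-test, unequal-variance (Welch) by default.

    Each group is either a vector of raw values or an ``(n, mean, sd)``
    summary, so the test can be reproduced directly from published group
    summaries. The statistic is oriented as ``mean_b - mean_a``; the 95%
    CI is ``mean_diff +/- t_{0.975, df} * SE`` with Satterthwaite degrees
    of freedom (or pooled-variance df when ``equal_var``).
    """
    na, ma, sa = _summarize(group_a)
    nb, mb, sb = _summarize(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    if sa <= 0 and sb <= 0:
        raise ValueError("t undefined: both group SDs are zero")
    va, vb = sa**2 / na, sb**2 / nb
    diff = mb - ma
    if equal_var:
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        dof = float(na + nb - 2)
    else:
        se = math.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    tcrit = stats.t.ppf(0.975, dof)
    return WelchResult(t_stat=t, df=dof, p_two_sided=float(p), mean_diff=diff,
                       ci95_low=diff - tcrit * se, ci95_high=diff + tcrit * se)


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (ties get average ranks)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks")
    return float(np.corrcoef(rx, ry)[0, 1])


_EXACT_N_MAX = 10


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of y-orderings."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = ry - ry.mean()
    n = len(rx)
    denom = n * ry.std()
    count = 0
    total = 0
    chunk: list = []

    def flush(chunk):
        perm = np.array(chunk)
        rhos = perm @ rx / denom
        return int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12)), len(chunk)

    for p in itertools.permutations(ry):
        chunk.append(p)
        if len(chunk) == 100_000:
            c, t = flush(chunk)
            count += c
            total += t
            chunk = []
    if chunk:
        c, t = flush(chunk)
        count += c
        total += t
    return count / total


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    ``rho`` is the Pearson correlation of mid-ranks. For n <= 10 the
    p-value is exact (full permutation enumeration); for larger n the
    usual t-approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rho = _rank_rho(x, y)
    if n <= _EXACT_N_MAX:
        p = _exact_spearman_p(x, y, rho)
        method = "exact-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
        method = "t-approximation"
    return SpearmanResult(rho=rho, p_two_sided=float(p), n=n, p_method=method)


def icc_absolute_agreement(ratings) -> ICCResult:
    """Single-measure absolute-agreement intraclass correlation, two-way
    mixed-effects model, with its 95% F-based confidence interval.

    From the two-way ANOVA decomposition of an n x k ratings matrix
    (subjects x raters):

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be an n_subjects x k_raters matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing or non-finite cells in ratings")
    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("zero total variance in ratings")
    if np.all(m == m[:, [0]]):
        # identical rater columns: perfect absolute agreement by definition
        return ICCResult(icc=1.0, ci95_low=1.0, ci95_high=1.0)
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    # residual computed directly (not by subtraction) for numerical safety
    resid = m - row_means[:, None] - col_means[None, :] + grand
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = float(np.sum(resid**2)) / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if mse == 0.0:
        # raters differ by constants only: degenerate interval
        return ICCResult(icc=float(icc), ci95_low=float(icc), ci95_high=float(icc))

    # McGraw-Wong interval for the absolute-agreement single-measure form
    alpha = 0.05
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(icc), ci95_low=float(lower), ci95_high=float(upper))


def fisher_exact(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table, two-sided by the
    probability-mass rule (sum over tables with fixed margins whose
    hypergeometric probability does not exceed the observed one)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(int)
        if np.any(t != t_int) or np.any(t_int < 0):
            raise ValueError("table must contain non-negative integers")
        t = t_int
    if t.sum() == 0:
        raise ValueError("table has no observations")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(p_two_sided=float(p),
                        table=((int(t[0, 0]), int(t[0, 1])),
                               (int(t[1, 0]), int(t[1, 1]))))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p). Requires 3 <= n <= 5000
    and a non-constant sample."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires a 1D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def rank_outlier_index(x, y) -> int:
    """Index of the most extreme point in rank space: the largest robust
    (median/MAD-standardized Euclidean) distance of the joint mid-ranks.

    A deterministic stand-in for visual outlier identification in a
    scatterplot; flagged as such in reports that use it.
    """
    rx = stats.rankdata(np.asarray(x, dtype=float))
    ry = stats.rankdata(np.asarray(y, dtype=float))
    def z(r):
        mad = stats.median_abs_deviation(r, scale="normal")
        scale = mad if mad > 0 else (np.std(r) or 1.0)
        return (r - np.median(r)) / scale
    d = z(rx) ** 2 + z(ry) ** 2
    return int(np.argmax(d))


_DESCRIPTIVE_VARS = ("age", "bmi", "sbp", "tchdl", "qrisk2", "df_mean")
GROUP_POS, GROUP_NEG = "WMH_pos", "WMH_neg"


def compare_groups(cohort: pd.DataFrame) -> dict:
    """Run the full group-comparison sequence on a cohort table.

    Emits per-group descriptives (mean +/- SD), Fisher's exact test on
    sex proportion, Welch's t on the averaged dimension (oriented so a
    positive t means the no-lesion group has the higher dimension),
    Spearman correlation of the QRISK2 score with the dimension (with and
    without the single most extreme rank-space point), inter-rater ICC,
    and the Shapiro-Wilk routing checks. Returns a JSON-serializable
    report.
    """
    required = {"group", "df_mean"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    pos = cohort[cohort["group"] == GROUP_POS]
    neg = cohort[cohort["group"] == GROUP_NEG]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >= 2 subjects per group (got {len(pos)} {GROUP_POS}, "
            f"{len(neg)} {GROUP_NEG})")

    report: dict = {"n_pos": int(len(pos)), "n_neg": int(len(neg))}

    desc = {}
    for var in _DESCRIPTIVE_VARS:
        if var not in cohort.columns:
            continue
        desc[var] = {
            GROUP_POS: {"mean": float(pos[var].mean()), "sd": float(pos[var].std(ddof=1))},
            GROUP_NEG: {"mean": float(neg[var].mean()), "sd": float(neg[var].std(ddof=1))},
        }
    report["descriptives"] = desc

    if "sex" in cohort.columns:
        tab = [[int((pos["sex"] == "M").sum()), int((pos["sex"] == "F").sum())],
               [int((neg["sex"] == "M").sum()), int((neg["sex"] == "F").sum())]]
        report["sex_fisher"] = fisher_exact(tab).to_dict()

    report["df_welch"] = welch_t(pos["df_mean"].to_numpy(),
                                 neg["df_mean"].to_numpy()).to_dict()

    normality = {}
    for label, vals in (("df_mean_pos", pos["df_mean"]), ("df_mean_neg", neg["df_mean"])):
        if len(vals) >= 3 and np.ptp(vals.to_numpy()) > 0:
            w, p = shapiro_wilk(vals.to_numpy())
            normality[label] = {"W": w, "p": p}
    if "qrisk2" in cohort.columns and np.ptp(cohort["qrisk2"].to_numpy()) > 0:
        w, p = shapiro_wilk(cohort["qrisk2"].to_numpy())
        normality["qrisk2"] = {"W": w, "p": p}
    report["shapiro_wilk"] = normality

    if "qrisk2" in cohort.columns:
        q = cohort["qrisk2"].to_numpy()
        d = cohort["df_mean"].to_numpy()
        report["qrisk_spearman"] = spearman(q, d).to_dict()
        out_idx = rank_outlier_index(q, d)
        keep = np.ones(len(q), dtype=bool)
        keep[out_idx] = False
        sens = spearman(q[keep], d[keep]).to_dict()
        sens["excluded_subject"] = str(cohort["subject_id"].iloc[out_idx]) \
            if "subject_id" in cohort.columns else int(out_idx)
        sens["outlier_rule"] = "stand-in: largest robust rank-space distance"
        report["qrisk_spearman_no_outlier"] = sens

    if {"df_rater1", "df_rater2"}.issubset(cohort.columns) and len(cohort) >= 5:
        ratings = cohort[["df_rater1", "df_rater2"]].to_numpy()
        try:
            report["interrater_icc"] = icc_absolute_agreement(ratings).to_dict()
        except ValueError as exc:
            report["interrater_icc"] = {"error": str(exc)}

    return report
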