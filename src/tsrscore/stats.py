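"""Observer-agreement statistics for comparing TSR scoring methods.

Implements the comparison battery used when a new scoring method (here the
semi- or fully automated TSR) is evaluated against visual estimation:
majority consensus over raters, stroma-low/-high dichotomization, Cohen's
kappa on the dichotomy, the intraclass correlation coefficient ICC(2,1)
(two-way random effects, absolute agreement, single measures) with its 95%
confidence interval, tie-aware Spearman rank correlation, Bland-Altman
limits of agreement, and t-tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError, UndefinedStatisticError
from .scores import NEEDS_MEETING, dichotomize  # noqa: F401  (re-exported)

ICC_MODEL = "two-way-random-absolute-single"  # ICC(2,1) / ICC(A,1)


# ---------------------------------------------------------------------------
# consensus

def consensus_score(scores) -> int | str:
    """Majority consensus of rater percentages.

    Returns the modal score when a strict majority of raters (2 of 3)
    agrees on it; otherwise the ``needs_meeting`` flag — such cases are
    resolved in a consensus meeting, never automatically.
    """
    values = [int(s) for s in scores]
    if len(values) < 3:
        raise InputError("consensus requires at least 3 raters")
    value, count = Counter(values).most_common(1)[0]
    if count > len(values) / 2:
        return value
    return NEEDS_MEETING


# ---------------------------------------------------------------------------
# Cohen's kappa

def cohens_kappa(a, b) -> float:
    """Unweighted Cohen's kappa between two label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the marginal distributions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise InputError("kappa requires at least 2 cases")
    labels = sorted(set(a.tolist()) | set(b.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "chance agreement is 1 (degenerate marginals); kappa undefined"
        )
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# ICC(2,1) with 95% CI

def icc(matrix, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Parameters
    ----------
    matrix
        Complete case x rater matrix (n cases, k raters).
    alpha
        1 - confidence level for the interval (default 95% CI).

    Returns
    -------
    (icc, (ci_low, ci_high))

    Notes
    -----
    From the two-way ANOVA mean squares (rows = cases MSR, columns = raters
    MSC, residual MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval uses the F-distribution bounds of this model
    with Satterthwaite degrees of freedom for the denominator.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InputError("ICC input must be a 2-D case x rater matrix")
    n, k = x.shape
    if k < 2 or n < 5:
        raise InputError("ICC requires >= 2 raters and >= 5 cases")
    if np.isnan(x).any():
        raise InputError("ICC requires a complete matrix")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom) or np.allclose(x, grand):
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    value = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measures)
    if value >= 1.0 - 1e-15:
        return float(value), (float(value), 1.0)
    a = k * value / (n * (1.0 - value))
    b = 1.0 + k * value * (n - 1) / (n * (1.0 - value))
    if mse == 0 and msc == 0:
        return float(value), (float(value), float(value))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_upp = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - n - k) * mse) + n * msr
    )
    upper = n * (f_upp * msr - mse) / (
        k * msc + (k * n - n - k) * mse + n * f_upp * msr
    )
    return float(value), (float(lower), float(upper))


# ---------------------------------------------------------------------------
# Spearman, Bland-Altman, t-tests

def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("Spearman requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant vector; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman agreement: mean difference and 95% limits of agreement.

    Returns (mean_diff, loa_low, loa_high) with limits at
    mean +/- 1.96 * SD of the paired differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InputError("Bland-Altman requires paired vectors, n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def t_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Paired or two-sample (Student) t-test.

    A paired test with zero variance of the differences is undefined and
    raised as such rather than returning NaN silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("t-test requires n >= 2 per sample")
    if paired:
        if x.shape != y.shape:
            raise InputError("paired t-test requires equal-length vectors")
        if np.std(x - y) == 0:
            raise UndefinedStatisticError(
                "paired differences have zero variance; t undefined"
            )
        res = sps.ttest_rel(x, y)
    else:
        res = sps.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# aggregate report

@dataclass(frozen=True)
class AgreementReport:
    """Full method-comparison battery between two percentage vectors."""

    kappa: float | None
    icc: float
    icc_ci95: tuple[float, float]
    icc_model: str
    spearman_rho: float
    spearman_p: float
    bland_altman: tuple[float, float, float]
    t_statistic: float | None
    t_p: float | None
    n_cases: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "icc": self.icc,
            "icc_ci95_low": self.icc_ci95[0],
            "icc_ci95_high": self.icc_ci95[1],
            "icc_model": self.icc_model,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "bland_altman_mean_diff": self.bland_altman[0],
            "bland_altman_loa_low": self.bland_altman[1],
            "bland_altman_loa_high": self.bland_altman[2],
            "t_statistic": self.t_statistic,
            "t_p": self.t_p,
            "n_cases": self.n_cases,
        }


def compare_methods(x, y, cutoff: float = 50.0) -> AgreementReport:
    """Compare two per-case stroma-percentage vectors (e.g. visual vs automated).

    Kappa is computed on the stroma-low/-high dichotomy at ``cutoff``; the
    ICC treats the second method as an additional rater.  Degenerate kappa
    or t statistics (constant labels, zero differences) are reported as None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("method comparison requires equal-length vectors")
    labels_x = [dichotomize(v, cutoff) for v in x]
    labels_y = [dichotomize(v, cutoff) for v in y]
    try:
        kappa = cohens_kappa(labels_x, labels_y)
    except UndefinedStatisticError:
        kappa = None
    icc_value, ci = icc(np.column_stack([x, y]))
    rho, p = spearman(x, y)
    ba = bland_altman(x, y)
    try:
        t, tp = t_test(x, y, paired=True)
    except UndefinedStatisticError:
        t, tp = None, None
    return AgreementReport(
        kappa=kappa, icc=icc_value, icc_ci95=ci, icc_model=ICC_MODEL,
        spearman_rho=rho, spearman_p=p, bland_altman=ba,
        t_statistic=t, t_p=tp, n_cases=int(x.size),
    )
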