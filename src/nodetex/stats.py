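"""Univariate, ROC and multivariate statistics for two-class lesion cohorts.

Implements the statistical battery usually reported alongside texture
analysis: Mann-Whitney U comparison with group medians/IQR, empirical
ROC analysis (AUC via the Mann-Whitney identity, DeLong confidence
intervals, Youden-optimal criterion with exact binomial CIs on
sensitivity/specificity), paired DeLong comparison of correlated ROC
curves, and linear multiple regression in the "enter" mode (all
predictors simultaneously) with per-coefficient tests, variance
inflation factors and R-squared.

The multivariate step is ordinary least squares on a 0/1 outcome rather
than a logistic model: it is the analysis whose R-squared / VIF block is
conventionally printed by clinical statistics packages for this design,
and its fitted values serve as the combined predictor score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MWResult",
    "ROCResult",
    "RegressionResult",
    "mann_whitney",
    "roc_analysis",
    "compare_rocs",
    "multiple_regression",
    "combined_roc",
]

#: combined sample size at or below which the exact Mann-Whitney
#: distribution is used (in the absence of ties)
EXACT_MW_LIMIT = 20


@dataclass
class MWResult:
    """Mann-Whitney comparison of two groups."""

    U: float
    p: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    method: str


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    # linear-interpolation percentiles (numpy default)
    return float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def mann_whitney(a, b) -> MWResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``U`` is the statistic of the first sample (number of pairs where a
    exceeds b, ties counting one half). The p-value is exact when the
    combined sample size is at most 20 and there are no ties, and uses
    the tie-corrected normal approximation (without continuity
    correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    pvalue = float(res.pvalue)
    if not np.isfinite(pvalue):
        # degenerate tie-corrected variance (all values identical)
        pvalue = 1.0
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    return MWResult(
        U=float(res.statistic),
        p=min(pvalue, 1.0),
        median_a=med_a,
        iqr_a=iqr_a,
        median_b=med_b,
        iqr_b=iqr_b,
        method=method,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    """Empirical ROC analysis at the Youden-optimal criterion.

    ``auc`` is oriented to be at least 0.5 (``flipped`` records whether
    the score had to be negated); ``auc_raw`` is the unflipped
    probability that a positive case scores higher than a negative one.
    The criterion is a strict ``>`` threshold on the (oriented) score.
    Sensitivity and specificity are proportions in [0, 1].
    """

    auc: float
    auc_ci: tuple[float, float]
    auc_raw: float
    flipped: bool
    youden: float
    criterion: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_positive: int
    n_negative: int
    p_auc_vs_half: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_mw(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability (concordant + half ties)."""
    ranks = _midrank(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    n1, n0 = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (r_all[:n1] - r_pos) / n0
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1
    return v10, v01


def _delong_var(pos: np.ndarray, neg: np.ndarray) -> float:
    v10, v01 = _delong_components(pos, neg)
    n1, n0 = pos.size, neg.size
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def roc_analysis(scores, labels, positive=None) -> ROCResult:
    """Empirical ROC analysis of a score against binary labels.

    The positive class defaults to the larger label value. The AUC
    equals the Mann-Whitney probability; its 95% CI uses the DeLong
    variance (Wald interval clipped to [0, 1]). The reported criterion
    maximizes the Youden index J = sensitivity + specificity - 1 over
    the observed score values, interpreted as a strict ``>`` threshold;
    J-ties resolve to the lowest criterion. Sensitivity/specificity CIs
    are Clopper-Pearson exact binomial intervals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    if positive is None:
        positive = classes[-1]
    pos = scores[labels == positive]
    neg = scores[labels != positive]

    auc_raw = _auc_mw(pos, neg)
    flipped = auc_raw < 0.5
    s = -scores if flipped else scores
    pos_s = s[labels == positive]
    neg_s = s[labels != positive]
    auc = _auc_mw(pos_s, neg_s)

    var = _delong_var(pos_s, neg_s)
    se = np.sqrt(var)
    z = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    p_half = 1.0 if se == 0 and auc == 0.5 else (
        float(2 * sps.norm.sf(abs(auc - 0.5) / se)) if se > 0 else 0.0
    )

    # Youden-optimal strict ">" criterion over observed score values
    cands = np.unique(s)
    best = None
    for c in cands:
        sens = float((pos_s > c).mean())
        spec = float((neg_s <= c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, crit, sens, spec = best
    if flipped:
        crit = -crit  # report on the original score scale
    k_sens = int(round(sens * pos_s.size))
    k_spec = int(round(spec * neg_s.size))
    return ROCResult(
        auc=auc,
        auc_ci=ci,
        auc_raw=auc_raw,
        flipped=flipped,
        youden=j,
        criterion=float(crit),
        sensitivity=sens,
        sensitivity_ci=_clopper_pearson(k_sens, pos_s.size),
        specificity=spec,
        specificity_ci=_clopper_pearson(k_spec, neg_s.size),
        n_positive=int(pos_s.size),
        n_negative=int(neg_s.size),
        p_auc_vs_half=p_half,
    )


def compare_rocs(scores1, scores2, labels, positive=None) -> dict:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both scores must be measured on the same lesions (paired). Returns
    the two-sided p-value together with the AUC difference and z
    statistic. Identical (or rank-identical) scores give delta = 0 and
    p = 1.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels)
    if s1.size != s2.size or s1.size != labels.size:
        raise ValueError("paired scores and labels must have equal length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if positive is None:
        positive = classes[-1]
    is_pos = labels == positive

    aucs = []
    v10s, v01s = [], []
    for s in (s1, s2):
        pos, neg = s[is_pos], s[~is_pos]
        aucs.append(_auc_mw(pos, neg))
        v10, v01 = _delong_components(pos, neg)
        v10s.append(v10)
        v01s.append(v01)
    n1 = int(is_pos.sum())
    n0 = int((~is_pos).sum())
    v10 = np.vstack(v10s)
    v01 = np.vstack(v01s)
    s10 = np.cov(v10) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n0 > 1 else np.zeros((2, 2))
    cov = s10 / n1 + s01 / n0
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-16:
        zstat = 0.0
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        zstat = delta / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(zstat)))
    return {"p": p, "delta_auc": float(delta), "z": float(zstat), "auc1": aucs[0], "auc2": aucs[1]}


# ---------------------------------------------------------------------------
# multiple regression


@dataclass
class RegressionResult:
    """OLS "enter"-model fit of a 0/1 outcome on a predictor table."""

    coefficients: pd.DataFrame  # coef, se, t, p, vif per term (incl. intercept)
    r2: float
    r2_adj: float
    multiple_r: float
    f_p: float
    fitted: np.ndarray
    predictors: list[str]


def multiple_regression(predictors: pd.DataFrame, outcome) -> RegressionResult:
    """Ordinary least squares with all predictors entered simultaneously.

    Reports per-predictor coefficient, standard error, t-test p-value
    and variance inflation factor (``VIF_j = 1 / (1 - R2_j)`` from
    regressing predictor j on the others, intercept included), together
    with R-squared, adjusted R-squared, the multiple correlation
    coefficient ``sqrt(R2)`` and the overall F-test p-value. The fitted
    values are the combined predictor score used by
    :func:`combined_roc`.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant predictor(s): {const_cols}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = []
        for c in X.columns:
            reduced = design.drop(columns=[c])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                collinear.append(c)
        raise ValueError(f"singular design; collinear columns: {collinear}")
    fit = sm.OLS(y, design).fit()
    exog = design.to_numpy()
    vifs = {"const": np.nan}
    if p == 1:
        vifs[X.columns[0]] = 1.0
    else:
        for j, c in enumerate(X.columns, start=1):
            vifs[c] = float(variance_inflation_factor(exog, j))
    coef = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "vif": pd.Series(vifs),
        }
    )
    coef.index.name = "term"
    return RegressionResult(
        coefficients=coef,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        multiple_r=float(np.sqrt(max(fit.rsquared, 0.0))),
        f_p=float(fit.f_pvalue) if fit.df_model > 0 else np.nan,
        fitted=np.asarray(fit.fittedvalues),
        predictors=list(X.columns),
    )


def combined_roc(regression: RegressionResult, labels, positive=None) -> ROCResult:
    """ROC analysis of the regression's fitted values (the combined score)."""
    return roc_analysis(regression.fitted, labels, positive=positive)
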