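"""Feature screening against MoCA and group-difference testing.

Two-stage screen:

1. correlation screen — Pearson when both the feature and the outcome
   pass a Shapiro-Wilk normality check (alpha = 0.05), Spearman rank
   correlation otherwise; features with p < 0.05 are retained;
2. covariate-adjusted univariate regression — each stage-1 survivor is
   entered alone into an OLS model of MoCA with age, height and BMI as
   covariates; features whose own term has p < 0.05 survive to
   multivariable modelling.

All screening p-values are raw (no multiplicity correction), a
deliberately liberal filter whose type-I behaviour is property-tested.
Group comparisons route to an independent t-test or a Mann-Whitney U
test by the same normality check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScreenResult",
    "UnivariateResult",
    "GroupComparison",
    "route_normality",
    "screen_correlations",
    "univariate_adjusted",
    "compare_groups",
    "screen_cascade",
]

ALPHA = 0.05
SHAPIRO_ALPHA = 0.05
COVARIATES = ("demographic__age", "demographic__height", "demographic__bmi")


@dataclass(frozen=True)
class ScreenResult:
    feature: str
    method: str  # 'pearson' or 'spearman'
    coefficient: float
    p_value: float
    retained: bool


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    beta_feature: float
    se_feature: float
    p_feature: float
    retained: bool


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    test: str  # 't_test' or 'mann_whitney'
    statistic: float
    p_value: float


def route_normality(x: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> str:
    """Classify a sample as 'normal' or 'non_normal' by Shapiro-Wilk."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality routing needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided p from the exact t transform of a correlation under H0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def _columnwise_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=0) * (yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    return r


def screen_correlations(
    candidates: pd.DataFrame, outcome: pd.Series, alpha: float = ALPHA
) -> pd.DataFrame:
    """Stage-1 screen: per-feature correlation with the outcome.

    Returns a frame with columns feature / method / coefficient /
    p_value / retained.  The Pearson branch is used only when both the
    feature and the outcome pass the normality check.
    """
    y = outcome.to_numpy(dtype=float)
    n = y.size
    outcome_normal = route_normality(y) == "normal"
    methods = []
    for col in candidates.columns:
        x = candidates[col].to_numpy(dtype=float)
        try:
            feat_normal = route_normality(x) == "normal"
        except ValueError:
            feat_normal = False
        methods.append("pearson" if (outcome_normal and feat_normal) else "spearman")
    methods = np.array(methods)

    X = candidates.to_numpy(dtype=float)
    coef = np.empty(X.shape[1])
    pearson_mask = methods == "pearson"
    if pearson_mask.any():
        coef[pearson_mask] = _columnwise_corr(X[:, pearson_mask], y)
    if (~pearson_mask).any():
        Xr = np.apply_along_axis(stats.rankdata, 0, X[:, ~pearson_mask])
        coef[~pearson_mask] = _columnwise_corr(Xr, stats.rankdata(y))
    pvals = _corr_pvalues(coef, n)
    return pd.DataFrame(
        {
            "feature": candidates.columns,
            "method": methods,
            "coefficient": coef,
            "p_value": pvals,
            "retained": pvals < alpha,
        }
    )


def univariate_adjusted(
    feature: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = ALPHA,
) -> UnivariateResult:
    """Stage-2 screen: OLS of the outcome on one feature plus covariates."""
    X = pd.concat([feature, covariates], axis=1)
    X = sm.add_constant(X, has_constant="add")
    model = sm.OLS(outcome.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    beta = float(model.params[1])
    se = float(model.bse[1])
    p = float(model.pvalues[1])
    cond = np.linalg.cond(X.to_numpy(dtype=float))
    if cond > 1e10:
        raise ValueError("collinear covariate design (condition number > 1e10)")
    return UnivariateResult(
        feature=str(feature.name),
        beta_feature=beta,
        se_feature=se,
        p_feature=p,
        retained=p < alpha,
    )


def compare_groups(feature: pd.Series, labels: pd.Series) -> GroupComparison:
    """Two-group comparison with normality-routed test choice."""
    groups = [feature[labels == g].to_numpy(dtype=float) for g in ("normal", "low")]
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    try:
        both_normal = all(route_normality(g) == "normal" for g in groups)
    except ValueError:
        both_normal = False
    if both_normal:
        stat, p = stats.ttest_ind(groups[0], groups[1])
        test = "t_test"
    else:
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        test = "mann_whitney"
    return GroupComparison(
        feature=str(feature.name), test=test, statistic=float(stat), p_value=float(p)
    )


def screen_cascade(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run both screening stages; returns (stage1, stage2, final candidates).

    The stage-2 candidate set is by construction a subset of the stage-1
    retentions.  Covariate columns are never screened against
    themselves.
    """
    screen_cols = [c for c in candidates.columns if c not in covariates.columns]
    stage1 = screen_correlations(candidates[screen_cols], outcome, alpha=alpha)
    survivors = stage1.loc[stage1["retained"], "feature"].tolist()
    rows = []
    for col in survivors:
        res = univariate_adjusted(candidates[col], outcome, covariates, alpha=alpha)
        rows.append(
            {
                "feature": res.feature,
                "beta_feature": res.beta_feature,
                "se_feature": res.se_feature,
                "p_feature": res.p_feature,
                "retained": res.retained,
            }
        )
    stage2 = pd.DataFrame(
        rows, columns=["feature", "beta_feature", "se_feature", "p_feature", "retained"]
    )
    final = stage2.loc[stage2["retained"], "feature"].tolist() if len(stage2) else []
    return stage1, stage2, final
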