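"""Stepwise multivariable regression of MoCA on screened candidates.

Forward selection with backward pruning on standardized data: at each
step the candidate with the smallest entry p-value below ``entry_p``
joins the model, then any retained term whose p-value has drifted above
``stay_p`` is dropped.  Age, height and BMI are forced into every model
as covariates and are never dropped; they are reported separately from
the selected terms.  Collinearity is summarized by variance inflation
factors (VIF = 1/(1-R^2) of each predictor on the others), with values
at or above 1.3 logged as warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = ["RegressionTerm", "StepwiseModel", "stepwise_fit", "compute_vif"]

VIF_WARN = 1.3


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    beta: float
    se: float
    t: float
    p: float
    vif: float


@dataclass(frozen=True)
class StepwiseModel:
    terms: tuple[RegressionTerm, ...]
    covariate_terms: tuple[RegressionTerm, ...]
    adjusted_r2: float
    entry_p: float
    stay_p: float
    note: str = ""

    @property
    def selected(self) -> list[str]:
        return [t.name for t in self.terms]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "beta": t.beta, "se": t.se, "t": t.t, "p": t.p, "vif": t.vif}
            for t in self.terms
        ]
        frame = pd.DataFrame(rows, columns=["term", "beta", "se", "t", "p", "vif"])
        frame.attrs["adjusted_r2"] = self.adjusted_r2
        return frame


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column of a predictor design.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the remaining
    columns (with intercept); perfectly collinear columns are flagged
    infinite.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = design.to_numpy(dtype=float)
    out = {}
    for i, col in enumerate(design.columns):
        others = np.column_stack([np.ones(len(X)), np.delete(X, i, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, X[:, i], rcond=None)
        resid = X[:, i] - others @ beta
        ss_res = float(resid @ resid)
        centered = X[:, i] - X[:, i].mean()
        ss_tot = float(centered @ centered)
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        if out[col] >= VIF_WARN:
            log.warning("VIF %.3f >= %.2f for predictor %s", out[col], VIF_WARN, col)
    return pd.Series(out, name="vif")


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design.to_numpy(dtype=float)).fit(), list(design.columns)


def stepwise_fit(
    candidates: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    entry_p: float = 0.05,
    stay_p: float = 0.10,
) -> StepwiseModel:
    """Forward-backward stepwise OLS with forced covariates.

    ``candidates`` and ``outcome`` should be standardized so the
    reported coefficients are standardized effects.  An empty candidate
    set (or one in which nothing meets the entry threshold) returns the
    covariate-only model with an explanatory note.
    """
    if covariates is None:
        covariates = pd.DataFrame(index=candidates.index)
    y = outcome.to_numpy(dtype=float)
    included: list[str] = []
    pool = list(candidates.columns)
    seen: set[frozenset[str]] = {frozenset()}

    tss = float(np.sum((y - y.mean()) ** 2))
    while True:
        changed = False
        if included:
            # degenerate stop: once the fit is numerically perfect,
            # further entry p-values carry no information
            model, _ = _fit_ols(y, pd.concat([covariates, candidates[included]], axis=1))
            if model.ssr <= 1e-10 * max(tss, 1.0):
                break
        # forward step
        best_p, best_col = np.inf, None
        for col in pool:
            X = pd.concat([covariates, candidates[included + [col]]], axis=1)
            model, names = _fit_ols(y, X)
            p = float(model.pvalues[names.index(col)])
            if p < best_p:
                best_p, best_col = p, col
        if best_col is not None and best_p < entry_p:
            included.append(best_col)
            pool.remove(best_col)
            changed = True
        # backward step(s)
        while included:
            X = pd.concat([covariates, candidates[included]], axis=1)
            model, names = _fit_ols(y, X)
            pvals = {c: float(model.pvalues[names.index(c)]) for c in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > stay_p:
                included.remove(worst)
                pool.append(worst)
                changed = True
            else:
                break
        if not changed:
            break
        # guard against forward/backward cycling: stop the first time a
        # model state recurs
        state = frozenset(included)
        if state in seen:
            break
        seen.add(state)

    note = "" if included else "no candidate met the entry threshold; covariate-only model"
    X = pd.concat([covariates, candidates[included]], axis=1)
    if X.shape[1] == 0:
        X = pd.DataFrame({"_null": np.zeros(len(y))}, index=candidates.index)
    model, names = _fit_ols(y, X)

    predictors = [c for c in X.columns if c != "_null"]
    if len(predictors) >= 2:
        vifs = compute_vif(X[predictors])
    else:
        vifs = pd.Series({c: 1.0 for c in predictors})

    def term(col: str) -> RegressionTerm:
        i = names.index(col)
        return RegressionTerm(
            name=col,
            beta=float(model.params[i]),
            se=float(model.bse[i]),
            t=float(model.tvalues[i]),
            p=float(model.pvalues[i]),
            vif=float(vifs.get(col, 1.0)),
        )

    return StepwiseModel(
        terms=tuple(term(c) for c in included),
        covariate_terms=tuple(term(c) for c in covariates.columns),
        adjusted_r2=float(model.rsquared_adj),
        entry_p=entry_p,
        stay_p=stay_p,
        note=note,
    )
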