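"""Nested, group-exclusive cross-validated classification of low-MoCA status.

Within each outer fold of a stratified group-wise 10-fold split,
feature standardization, recursive feature elimination (RFE with an
L2-logistic base estimator, down to at most 20 features in steps of 2)
and cross-validated RFE (subset size chosen by mean inner-fold ROC-AUC
over a 5-fold stratified group-wise split, minimum 5 features, with a
one-standard-error parsimony rule breaking statistically tied sizes
toward fewer features) are all fitted on the training rows only; the
held-out fold is scored with the training-fitted scaler and selector.

Four model families are supported: L2 logistic regression (C = 0.5),
linear and RBF-kernel SVMs (C = 1.0, 'scale' kernel width, probabilities
via a sigmoid score-to-probability mapping fitted on training-fold
decision scores), and gradient-boosted trees (100 rounds, depth 3,
learning rate 0.05, 0.8 row/column subsampling, L2 penalty 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import schema
from ._utils import derive_seed

__all__ = [
    "CvConfig",
    "ModelSpec",
    "MODEL_FAMILIES",
    "CvResult",
    "make_folds",
    "rfe_select",
    "rfecv_select",
    "fit_predict",
    "evaluate",
    "bootstrap_ci",
    "nested_cv",
    "single_feature_roc",
]

POSITIVE_LABEL = "low"  # the low-MoCA group is the positive class

MODEL_FAMILIES = ("logistic_l2", "svm_linear", "svm_rbf", "gradient_boosted_trees")


@dataclass(frozen=True)
class CvConfig:
    outer_folds: int = 10
    inner_folds: int = 5
    rfe_max_features: int = 20
    rfe_step: int = 2
    rfecv_min_features: int = 5
    rfecv_step: int = 2
    seed: int = 42
    bootstrap_reps: int = 1000
    configuration: str = "combined"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.rfecv_min_features > self.rfe_max_features:
            raise ValueError("rfecv_min_features must be <= rfe_max_features")
        if self.configuration not in schema.CONFIGURATION_CATEGORIES:
            raise ValueError(f"unknown configuration {self.configuration!r}")

    def validate_groups(self, labels: pd.Series) -> None:
        counts = labels.value_counts()
        if len(counts) < 2:
            raise ValueError("both classes must be present")
        if self.outer_folds > counts.min():
            raise ValueError(
                f"outer_folds={self.outer_folds} exceeds the smaller group size "
                f"({counts.min()})"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Immutable hyperparameters for one model family."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def default_model_specs() -> list[ModelSpec]:
    return [ModelSpec(family=f) for f in MODEL_FAMILIES]


def _base_logistic(seed: int) -> LogisticRegression:
    # L2 penalty (the estimator's default), C = 0.5, liblinear solver
    return LogisticRegression(
        C=0.5, solver="liblinear", max_iter=10_000, random_state=seed
    )


def _build_estimator(spec: ModelSpec, seed: int):
    if spec.family == "logistic_l2":
        return _base_logistic(seed)
    if spec.family == "svm_linear":
        return CalibratedClassifierCV(
            SVC(kernel="linear", C=1.0, random_state=seed), method="sigmoid", cv=3
        )
    if spec.family == "svm_rbf":
        return CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
            method="sigmoid",
            cv=3,
        )
    if spec.family == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.05,
            subsample=0.8,
            colsample_bytree=0.8,
            reg_lambda=1.0,
            objective="binary:logistic",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
        )
    raise ValueError(spec.family)


@dataclass(frozen=True)
class CvResult:
    family: str
    configuration: str
    fold_metrics: pd.DataFrame  # per-outer-fold accuracy / roc_auc / n_selected
    selected_features: tuple[tuple[str, ...], ...]
    stability: pd.Series  # per-feature selection frequency in [0, 1]
    pooled_predictions: pd.Series  # out-of-fold probability per participant
    labels: pd.Series
    metrics: dict[str, float]
    metric_cis: dict[str, tuple[float, float]]
    roc_points: pd.DataFrame

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["roc_auc"].mean())


def _binary(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


def make_folds(
    labels: pd.Series,
    participant_ids: Sequence[str],
    n_folds: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified group-wise folds over participants.

    Each participant contributes one row, so grouping by participant id
    guarantees no identifier ever appears on both sides of a fold;
    stratification keeps per-fold class proportions within one
    participant of the global balance.
    """
    y = _binary(labels)
    groups = np.asarray(participant_ids)
    if len(groups) != len(y):
        raise ValueError("labels and participant_ids must align")
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X_dummy = np.zeros((len(y), 1))
    folds = [
        (np.asarray(tr), np.asarray(te))
        for tr, te in splitter.split(X_dummy, y, groups=groups)
    ]
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a fold's training set lost one class; use fewer folds")
    return folds


def rfe_select(
    train_X: pd.DataFrame,
    train_y: pd.Series | np.ndarray,
    max_features: int = 20,
    step: int = 2,
    seed: int = 42,
) -> list[str]:
    """RFE with L2 logistic regression down to at most ``max_features``.

    When the candidate pool is already no larger than the cap, every
    feature is retained (the eliminator has nothing to do).
    """
    y = _binary(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold has a single class")
    if train_X.shape[1] <= max_features:
        return list(train_X.columns)
    selector = RFE(
        _base_logistic(seed), n_features_to_select=max_features, step=step
    )
    selector.fit(train_X.to_numpy(dtype=float), y)
    return list(train_X.columns[selector.support_])


def _elimination_order(X: pd.DataFrame, y: np.ndarray, min_features: int, step: int, seed: int) -> np.ndarray:
    """Column indices ordered by RFE survival (longest-surviving first)."""
    rfe = RFE(_base_logistic(seed), n_features_to_select=min_features, step=step)
    rfe.fit(X.to_numpy(dtype=float), y)
    return np.argsort(rfe.ranking_, kind="stable")


def rfecv_select(
    train_X: pd.DataFrame,
    train_y: pd.Series | np.ndarray,
    groups: Sequence[str],
    inner_folds: int = 5,
    min_features: int = 5,
    step: int = 2,
    seed: int = 42,
) -> list[str]:
    """Cross-validated RFE over a stratified group-wise inner split.

    For every candidate subset size (``min_features`` upward in steps of
    ``step``) the mean inner-fold ROC-AUC is computed along each fold's
    own elimination path; the retained size is the smallest one whose
    mean score comes within one standard error of the best — the
    one-standard-error parsimony rule, which reduces the exact-tie
    break toward fewer features to a statistical rule: sizes whose
    scores are indistinguishable from the maximum count as tied, so
    feature sets without real signal collapse to ``min_features``.
    Deterministic given seed and data.
    """
    y = _binary(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold has a single class")
    if train_X.shape[1] <= min_features:
        return list(train_X.columns)
    sizes = list(range(min_features, train_X.shape[1] + 1, step))
    if sizes[-1] != train_X.shape[1]:
        sizes.append(train_X.shape[1])
    inner = StratifiedGroupKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    scores = np.zeros((inner_folds, len(sizes)))
    for fi, (tr, te) in enumerate(inner.split(train_X, y, groups=np.asarray(groups))):
        Xtr, Xte = train_X.iloc[tr], train_X.iloc[te]
        order = _elimination_order(Xtr, y[tr], min_features, step, seed)
        for si, k in enumerate(sizes):
            cols = train_X.columns[np.sort(order[:k])]
            est = _base_logistic(seed).fit(Xtr[cols].to_numpy(dtype=float), y[tr])
            proba = est.predict_proba(Xte[cols].to_numpy(dtype=float))[:, 1]
            scores[fi, si] = roc_auc_score(y[te], proba)
    mean = scores.mean(axis=0)
    best = int(np.argmax(mean))
    se = float(scores[:, best].std(ddof=1) / np.sqrt(inner_folds))
    chosen_size = next(
        sizes[si] for si in range(len(sizes)) if mean[si] >= mean[best] - se
    )
    order = _elimination_order(train_X, y, min_features, step, seed)
    return list(train_X.columns[np.sort(order[:chosen_size])])


def fit_predict(
    train_X: pd.DataFrame,
    train_y: pd.Series | np.ndarray,
    test_X: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 42,
) -> np.ndarray:
    """Fit one family on the training fold and return test probabilities.

    Standardization is fitted on the training rows only and applied
    unchanged to the test rows (no test-side refit).
    """
    y = _binary(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold has a single class")
    scaler = StandardScaler().fit(train_X.to_numpy(dtype=float))
    Xtr = scaler.transform(train_X.to_numpy(dtype=float))
    Xte = scaler.transform(test_X.to_numpy(dtype=float))
    est = _build_estimator(spec, seed)
    est.fit(Xtr, y)
    proba = est.predict_proba(Xte)[:, 1]
    return np.clip(proba, 0.0, 1.0)


def _safe_ratio(num: float, den: float) -> float:
    return float("nan") if den == 0 else num / den


def evaluate(
    pooled: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Accuracy, rank-based ROC-AUC, sensitivity, specificity, PPV, NPV.

    Ratios with a zero denominator are reported as NaN rather than
    being clamped.
    """
    p = np.asarray(pooled, dtype=float)
    y = _binary(labels)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must align")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return {
        "accuracy": _safe_ratio(tp + tn, len(y)),
        "roc_auc": auc,
        "sensitivity": _safe_ratio(tp, tp + fn),
        "specificity": _safe_ratio(tn, tn + fp),
        "ppv": _safe_ratio(tp, tp + fp),
        "npv": _safe_ratio(tn, tn + fn),
    }


def bootstrap_ci(
    pooled: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    metric: str,
    reps: int = 1000,
    seed: int = 42,
    alpha: float = 0.05,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Percentile bootstrap CI over participant-level resamples.

    Returns (NaN, NaN) when the metric is undefined in more than half
    of the resamples.
    """
    if reps < 100:
        raise ValueError("bootstrap needs reps >= 100")
    p = np.asarray(pooled, dtype=float)
    y = _binary(labels)
    n = len(y)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for b in range(reps):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if len(np.unique(yb)) < 2 and metric == "roc_auc":
            values[b] = np.nan
            continue
        values[b] = evaluate(p[idx], yb, threshold=threshold)[metric]
    defined = values[np.isfinite(values)]
    if defined.size <= reps / 2:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(defined, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi))


def _configuration_columns(table: pd.DataFrame, configuration: str) -> list[str]:
    cats = schema.CONFIGURATION_CATEGORIES[configuration]
    cols = schema.columns_in(table.columns, cats)
    # columns without a known category prefix (e.g. synthetic test beds)
    # are visible to every configuration
    known = set().union(*[set(v) for v in schema.CONFIGURATION_CATEGORIES.values()])
    cols += [c for c in table.columns if schema.category_of(c) not in known]
    if not cols:
        raise ValueError(f"no columns available for configuration {configuration!r}")
    return cols


def nested_cv(
    table: pd.DataFrame,
    labels: pd.Series,
    config: CvConfig = CvConfig(),
    specs: Iterable[ModelSpec] | None = None,
) -> dict[str, CvResult]:
    """Run the full nested cross-validation for one configuration.

    ``table`` is the imputed (complete, unstandardized) participant
    feature table; the configuration selects its column subset by
    category.  Per outer fold, scaling and the two-stage feature
    selection are fitted on training rows only; pooled out-of-fold
    probabilities give the headline metrics and the per-feature
    selection frequencies give the stability profile.
    """
    if specs is None:
        specs = default_model_specs()
    specs = list(specs)
    config.validate_groups(labels)
    cols = _configuration_columns(table, config.configuration)
    X = table[cols]
    ids = list(table.index.astype(str))
    folds = make_folds(labels, ids, config.outer_folds, config.seed)

    selections: list[tuple[str, ...]] = []
    fold_rows: dict[str, list[dict[str, float]]] = {s.family: [] for s in specs}
    pooled: dict[str, np.ndarray] = {
        s.family: np.full(len(X), np.nan) for s in specs
    }
    y_all = _binary(labels)

    for fold_idx, (tr, te) in enumerate(folds):
        Xtr_raw, Xte_raw = X.iloc[tr], X.iloc[te]
        scaler = StandardScaler().fit(Xtr_raw.to_numpy(dtype=float))
        Xtr = pd.DataFrame(
            scaler.transform(Xtr_raw.to_numpy(dtype=float)),
            index=Xtr_raw.index,
            columns=X.columns,
        )
        fold_seed = derive_seed(config.seed, f"fold{fold_idx}")
        subset = rfe_select(
            Xtr,
            y_all[tr],
            max_features=config.rfe_max_features,
            step=config.rfe_step,
            seed=fold_seed,
        )
        subset = rfecv_select(
            Xtr[subset],
            y_all[tr],
            groups=[ids[i] for i in tr],
            inner_folds=config.inner_folds,
            min_features=config.rfecv_min_features,
            step=config.rfecv_step,
            seed=fold_seed,
        )
        selections.append(tuple(subset))
        for spec in specs:
            proba = fit_predict(
                Xtr_raw[subset], y_all[tr], Xte_raw[subset], spec, seed=fold_seed
            )
            pooled[spec.family][te] = proba
            fold_auc = (
                float(roc_auc_score(y_all[te], proba))
                if len(np.unique(y_all[te])) == 2
                else float("nan")
            )
            fold_rows[spec.family].append(
                {
                    "fold": fold_idx,
                    "accuracy": float(
                        np.mean((proba >= config.threshold).astype(int) == y_all[te])
                    ),
                    "roc_auc": fold_auc,
                    "n_selected": len(subset),
                }
            )

    counts = pd.Series(0.0, index=cols)
    for subset in selections:
        for c in subset:
            counts[c] += 1.0
    stability = counts / config.outer_folds

    results: dict[str, CvResult] = {}
    for spec in specs:
        probs = pd.Series(pooled[spec.family], index=table.index, name="probability")
        metrics = evaluate(probs, labels, threshold=config.threshold)
        cis = {
            m: bootstrap_ci(
                probs,
                labels,
                m,
                reps=config.bootstrap_reps,
                seed=derive_seed(config.seed, f"boot_{spec.family}_{m}"),
                threshold=config.threshold,
            )
            for m in ("sensitivity", "specificity", "ppv", "npv")
        }
        fpr, tpr, thr = roc_curve(y_all, probs.to_numpy())
        roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        results[spec.family] = CvResult(
            family=spec.family,
            configuration=config.configuration,
            fold_metrics=pd.DataFrame(fold_rows[spec.family]),
            selected_features=tuple(selections),
            stability=stability,
            pooled_predictions=probs,
            labels=labels,
            metrics=metrics,
            metric_cis=cis,
            roc_points=roc_points,
        )
    return results


def single_feature_roc(
    feature: pd.Series, labels: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC and ROC points for one feature, orientation as-is.

    No flipping is applied, so an AUC below 0.5 (feature lower in the
    positive class) is reported as such.
    """
    x = feature.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant feature has no ROC curve")
    y = _binary(labels)
    auc = float(roc_auc_score(y, x))
    fpr, tpr, thr = roc_curve(y, x)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
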