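"""Participant-level table assembly: MoCA adjustment and grouping, trial
averaging, cognitive-score exclusion, kNN imputation and z-scoring.

The container is a thin wrapper around a pandas DataFrame whose columns
carry category prefixes (see :mod:`gaitcog.schema`); all operations are
deterministic functions of their inputs so assembly can be re-run
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from . import schema

log = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "ImputationSpec",
    "adjust_moca",
    "assign_group",
    "average_trials",
    "exclude_cognitive",
    "knn_impute",
    "zscore",
]


@dataclass(frozen=True)
class CohortTable:
    """Participants x features, with missingness mask, outcome and label.

    ``data`` holds every feature column (category-prefixed) including
    metadata columns; ``outcome`` is the education-adjusted MoCA score
    and ``label`` the derived normal/low grouping.
    """

    data: pd.DataFrame
    mask: pd.DataFrame | None
    outcome: pd.Series
    label: pd.Series

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        if not self.outcome.index.equals(self.data.index):
            raise ValueError("outcome index must match data index")

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def candidate_frame(self) -> pd.DataFrame:
        """The candidate feature pool: all non-meta, non-cognitive columns."""
        cols = [
            c
            for c in self.data.columns
            if schema.category_of(c) != "meta" and c not in schema.COGNITIVE_COLUMNS
        ]
        return self.data[cols]

    def block(self, category: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if schema.category_of(c) == category]
        return self.data[cols]

    def block_counts(self) -> dict[str, int]:
        return schema.block_counts(self.data.columns)


@dataclass(frozen=True)
class ImputationSpec:
    """k-nearest-neighbour imputation parameters.

    Neighbour distance is the nan-aware Euclidean distance over
    standardized co-observed columns, rescaled by the number of
    co-observed columns, and each missing cell is replaced by the
    unweighted mean of the feature over the k nearest participants with
    that feature observed.
    """

    k: int = 5

    def validate(self, n_participants: int) -> None:
        if self.k < 1 or self.k >= n_participants:
            raise ValueError(
                f"k must satisfy 1 <= k < n_participants={n_participants}, got {self.k}"
            )


def adjust_moca(raw: int, education_years: float) -> int:
    """Education-adjusted MoCA: +1 point for <= 6 years of schooling, capped at 30."""
    if not 0 <= raw <= 30:
        raise ValueError(f"MoCA score must lie in [0, 30], got {raw}")
    if education_years <= 6:
        return min(int(raw) + 1, 30)
    return int(raw)


def assign_group(adjusted: int) -> str:
    """Low-MoCA iff the adjusted score is below 26."""
    if not 0 <= adjusted <= 30:
        raise ValueError(f"adjusted MoCA must lie in [0, 30], got {adjusted}")
    return "low" if adjusted < 26 else "normal"


def average_trials(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Average repeated trials to one value per (participant, feature).

    Expects a long-format frame with columns ``participant``,
    ``feature``, ``value`` (and any number of other identifier columns,
    e.g. ``repeat``).  Missing repeats are ignored; a cell is missing
    only when every repeat is missing.
    """
    required = {"participant", "feature", "value"}
    if not required.issubset(per_trial.columns):
        raise ValueError(f"long-format frame must have columns {sorted(required)}")
    wide = (
        per_trial.groupby(["participant", "feature"], sort=False)["value"]
        .mean()
        .unstack("feature")
    )
    wide.index.name = "participant_id"
    return wide


def exclude_cognitive(table: CohortTable) -> CohortTable:
    """Drop direct cognitive test columns from the feature set.

    The outcome (adjusted MoCA) is retained separately on the table, so
    downstream stages can never leak the cognitive score back into the
    candidate pool.
    """
    present = [c for c in schema.COGNITIVE_COLUMNS if c in table.data.columns]
    if not present:
        return table
    data = table.data.drop(columns=present)
    mask = table.mask.drop(columns=present) if table.mask is not None else None
    return replace(table, data=data, mask=mask)


def knn_impute(table: CohortTable, spec: ImputationSpec = ImputationSpec()) -> CohortTable:
    """Replace each missing cell by the mean over the k most similar
    participants, measured in standardized co-observed feature space.

    Columns are standardized with nan-aware moments before the distance
    computation so that no single scale dominates, and imputed values
    are mapped back to the original units.  Deterministic given the
    table.  If fewer than k donors exist for a cell, all available
    donors are used with a warning.
    """
    spec.validate(table.n_participants)
    data = table.data
    numeric = data.select_dtypes(include=[np.number])
    if not numeric.isna().any().any():
        return table
    n_complete = (~numeric.isna()).sum(axis=0).min()
    if n_complete <= spec.k:
        log.warning("fewer than k=%d complete donors for some columns", spec.k)
    mu = numeric.mean(skipna=True)
    sd = numeric.std(skipna=True, ddof=0).replace(0.0, 1.0)
    standardized = (numeric - mu) / sd
    imputer = KNNImputer(n_neighbors=spec.k, weights="uniform", metric="nan_euclidean")
    filled = pd.DataFrame(
        imputer.fit_transform(standardized.to_numpy()),
        index=numeric.index,
        columns=numeric.columns,
    )
    restored = filled * sd + mu
    out = data.copy()
    out[numeric.columns] = restored
    return replace(table, data=out)


def zscore(table: CohortTable, drop_constant: bool = True) -> CohortTable:
    """Standardize every numeric column to mean 0, population SD 1.

    Population (ddof=0) SD is used so standardization is an exact
    idempotent transform; constant columns carry no information and are
    dropped from the table with a log entry.
    """
    data = table.data
    numeric = data.select_dtypes(include=[np.number])
    if numeric.isna().any().any():
        raise ValueError("z-scoring requires an imputed (complete) table")
    mu = numeric.mean()
    sd = numeric.std(ddof=0)
    constant = sd[sd == 0.0].index.tolist()
    if constant and drop_constant:
        log.info("dropping %d constant columns: %s", len(constant), constant[:5])
    keep = [c for c in numeric.columns if c not in constant]
    transformed = (numeric[keep] - mu[keep]) / sd[keep]
    out = data.drop(columns=constant).copy() if drop_constant else data.copy()
    out[keep] = transformed
    mask = table.mask
    if mask is not None and drop_constant and constant:
        mask = mask.drop(columns=[c for c in constant if c in mask.columns])
    return replace(table, data=out, mask=mask)
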