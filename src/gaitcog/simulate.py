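"""Synthetic Parkinson's-disease cohort and raw gait-signal generator.

The generator emulates the data structure the analysis assumes, so every
downstream stage (screening, stepwise regression, network estimation,
nested-CV classification) is testable without access to clinical data:

* a participant-level table of 434 candidate variables (5 demographic,
  21 clinical, 10 physical-function/lifestyle, 38 motion-capture and 360
  wearable-sensor features) with realistic marginal means and spreads;
* a latent layer that plants a linear coupling, on standardized scales,
  between the MoCA score and three motor drivers — motor-exam severity
  (UPDRS Part III), stride length of the more affected side during
  preferred-speed inward turning, and peak ankle jerk of the less
  affected side during forward walking — plus an independent age effect;
* raw quasi-periodic IMU signals (60 Hz, six placements, six task
  conditions) and simplified marker trajectories (100 Hz) whose extracted
  features respond monotonically to the latent gait parameters.

Cognition model
---------------
With ``u`` (motor exam), ``s`` (turn stride length) and ``j`` (ankle
jerk) standardized driver scores that share a latent motor-severity
factor, the standardized cognition score is

    z = b_u * u + b_s * s + b_j * j - g_age * a + sigma * eps

where ``a`` is the standardized age component and ``eps`` independent
Gaussian noise.  ``sigma`` defaults to the value that makes ``z`` unit
variance, so the planted ``b`` coefficients *are* the population
standardized regression coefficients.  MoCA is the rounded, clipped
integer ``25.8 + 3.0 * z``; group sizes are fixed exactly by
group-conditional rejection sampling on the education-adjusted score
(score < 26 defines the low-MoCA group), mirroring a design with fixed
group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import schema
from ._utils import rng_from
from .features import ImuRecording, MocapTrial

__all__ = [
    "CohortSpec",
    "SignalSpec",
    "LatentProfile",
    "planted_r2",
    "generate_cohort",
    "generate_imu_trials",
    "generate_mocap_trial",
    "generate_mocap_trials",
    "inject_missingness",
    "make_planted_binary_cohort",
    "TABLE_DEMOGRAPHICS",
]

# Latent loadings of the three drivers on the shared motor-severity factor.
LOADING_UPDRS = 0.7
LOADING_STRIDE = -0.5
LOADING_JERK = 0.5

# Standardized direct age effect on cognition (independent of the motor
# drivers); sized so that the driver + covariate model explains roughly
# 35-40% of MoCA variance, the magnitude reported for cohorts like this.
AGE_EFFECT = 0.354

MOCA_MEAN = 25.8
MOCA_SD = 3.0

# Group-wise demographic reference moments (normal-MoCA n=60 / low-MoCA
# n=42 cohort): mean and SD per group for the headline demographics.
TABLE_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"normal": (65.83, 7.52), "low": (71.24, 5.36)},
    "height": {"normal": (161.47, 8.16), "low": (158.79, 8.66)},
    "weight": {"normal": (62.95, 11.89), "low": (62.82, 8.67)},
    "education_years": {"normal": (12.73, 3.25), "low": (10.36, 3.62)},
}

# Pooled (mean, SD, loading-on-severity) per clinical / physical column.
# Pooled moments combine the two groups' reference values; loadings give
# severity-linked instruments realistic correlations with the motor
# drivers (and hence, indirectly, with MoCA) without touching the
# cognition residual.
_CLINICAL_PARAMS: dict[str, tuple[float, float, float]] = {
    "clinical__hoehn_yahr": (1.96, 0.72, 0.50),
    "clinical__updrs_total": (54.51, 23.26, 0.80),
    "clinical__updrs_i": (10.09, 5.23, 0.35),
    "clinical__updrs_ii": (12.89, 7.22, 0.55),
    "clinical__updrs_iv": (1.71, 2.68, 0.10),
    "clinical__symptom_duration": (5.70, 4.38, 0.25),
    "clinical__treatment_duration": (4.55, 4.22, 0.25),
    "clinical__ledd": (545.46, 290.54, 0.20),
    "clinical__bdi": (14.0, 8.0, 0.30),
    "clinical__bai": (12.0, 8.0, 0.30),
    "clinical__pdss2": (15.0, 9.0, 0.25),
    "clinical__ess": (7.0, 4.5, 0.20),
    "clinical__fss": (4.2, 1.4, 0.30),
    "clinical__fall_history": (0.8, 1.3, 0.35),
    "clinical__fes": (30.0, 10.0, 0.40),
    "clinical__see": (55.0, 20.0, -0.30),
    "clinical__nfogq": (6.0, 7.0, 0.45),
    "clinical__nmss": (35.0, 25.0, 0.40),
    "clinical__pdq39": (30.0, 20.0, 0.50),
    "physical_lifestyle__grip_strength": (26.0, 8.0, -0.25),
    "physical_lifestyle__ftsts": (12.0, 4.0, 0.40),
    "physical_lifestyle__six_mwt": (420.0, 90.0, -0.45),
    "physical_lifestyle__sppb": (10.0, 1.8, -0.45),
    "physical_lifestyle__mini_best": (22.0, 4.0, -0.50),
    "physical_lifestyle__nq": (60.0, 12.0, 0.0),
    "physical_lifestyle__sf36_total": (65.0, 18.0, -0.35),
    "physical_lifestyle__sf36_physical": (62.0, 20.0, -0.40),
    "physical_lifestyle__sf36_mental": (68.0, 18.0, -0.25),
    "physical_lifestyle__ipaq": (2500.0, 2200.0, -0.20),
}

# Reference scale of the three planted driver columns (pooled mean, SD).
_DRIVER_SCALE = {
    "clinical__updrs_iii": (29.45, 15.30),
    "mocap__TurnPS_IMA_SLM": (0.55, 0.12),
    "wearable__FW_LANK_MaxJerk": (35.0, 10.0),
}

DRIVER_COLUMNS = tuple(_DRIVER_SCALE)

# Gait noise-column plausibility scales by feature type, plus a mild
# severity loading so that a realistic fraction of gait features shows
# weak marginal MoCA correlations.
_MOCAP_BASE = {
    "Speed": (1.05, 0.20, -0.30),
    "SLM": (1.10, 0.15, -0.30),
    "SLL": (1.10, 0.15, -0.30),
    "SSM": (38.0, 3.0, -0.20),
    "SSL": (38.0, 3.0, -0.20),
    "DS": (24.0, 5.0, 0.25),
    "CoordMALA": (8.0, 3.0, 0.15),
    "CoordLAMA": (8.0, 3.0, 0.15),
}
_MOCAP_TASK_FACTOR = {
    "FW": 1.0,
    "BW": 0.75,
    "TurnPS_IMA": 0.50,
    "TurnPS_OMA": 0.52,
    "TurnFS_IMA": 0.60,
    "TurnFS_OMA": 0.62,
}

_WEARABLE_BASE = {
    "MaxJerk": (35.0, 10.0, 0.25),
    "MaxAngJerk": (250.0, 80.0, 0.25),
    "MeanAcc": (1.8, 0.40, -0.15),
    "MaxAcc": (4.5, 1.00, -0.15),
    "RMSAcc": (2.0, 0.45, -0.15),
    "MeanGyr": (1.2, 0.30, -0.15),
    "MaxGyr": (3.0, 0.70, -0.15),
    "RMSGyr": (1.4, 0.35, -0.15),
    "SampEnAcc": (0.90, 0.25, 0.20),
    "SampEnGyr": (0.80, 0.25, 0.20),
}
_PLACEMENT_FACTOR = {
    "MANK": 1.0,
    "LANK": 1.0,
    "MELB": 0.55,
    "LELB": 0.55,
    "T10": 0.35,
    "PSIS": 0.40,
}

PLACEMENT_ACC_SCALE = {"MANK": 3.0, "LANK": 3.0, "MELB": 1.5, "LELB": 1.5, "T10": 1.0, "PSIS": 1.2}
PLACEMENT_GYR_SCALE = {"MANK": 2.0, "LANK": 2.0, "MELB": 1.0, "LELB": 1.0, "T10": 0.6, "PSIS": 0.8}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator configuration.

    The standardized driver effects default to the planted values
    (-0.252 motor exam, +0.258 turning stride length, -0.180 ankle
    jerk); ``residual_sd=None`` auto-calibrates the cognition noise so
    the standardized cognition score has unit variance, making the
    planted effects the true standardized coefficients.
    """

    n_normal: int = 60
    n_low: int = 42
    seed: int = 0
    beta_updrs: float = -0.252
    beta_stride: float = 0.258
    beta_jerk: float = -0.180
    residual_sd: float | None = None
    missing_rate: float = 0.02
    demographic_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: TABLE_DEMOGRAPHICS
    )

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_low <= 0:
            raise ValueError(
                f"group sizes must be positive, got n_normal={self.n_normal}, "
                f"n_low={self.n_low}"
            )
        if self.n_normal + self.n_low < 20:
            raise ValueError("cohort must have at least 20 participants")
        if not 0 <= self.missing_rate < 0.05:
            raise ValueError(f"missing_rate must lie in [0, 0.05), got {self.missing_rate}")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_low

    def effective_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return float(self.residual_sd)
        explained = planted_r2(self) + AGE_EFFECT**2
        if explained >= 0.95:
            raise ValueError("planted effects leave no room for residual noise")
        return math.sqrt(1.0 - explained)


def _driver_cov() -> np.ndarray:
    loadings = np.array([LOADING_UPDRS, LOADING_STRIDE, LOADING_JERK])
    cov = np.outer(loadings, loadings)
    np.fill_diagonal(cov, 1.0)
    return cov


def planted_r2(spec: CohortSpec) -> float:
    """Population R^2 of standardized cognition on the three drivers."""
    beta = np.array([spec.beta_updrs, spec.beta_stride, spec.beta_jerk])
    return float(beta @ _driver_cov() @ beta)


@dataclass(frozen=True)
class LatentProfile:
    """Latent per-participant state that the raw-signal generators realize."""

    participant_id: str
    latent_motor_severity: float
    latent_cognition: float
    more_affected_side: str  # 'left' or 'right'
    stride_frequency: float  # Hz (full gait cycles per second)
    stride_length_true: Mapping[str, float]  # metres per side ('more'/'less')
    jerk_scale_true: float  # multiplicative, applied at the less affected ankle
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.stride_frequency <= 1.5):
            raise ValueError("stride_frequency must lie in [0.5, 1.5] Hz")
        if not (
            np.isfinite(self.latent_motor_severity)
            and np.isfinite(self.latent_cognition)
        ):
            raise ValueError("latent scores must be finite")


@dataclass(frozen=True)
class SignalSpec:
    """Raw-signal generator configuration."""

    fs_imu: float = 60.0
    fs_mocap: float = 100.0
    trial_duration: float = 10.0
    n_repeats: int = 3
    turn_angle: float = 360.0  # degrees
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.5, 0.25)
    noise_sd: float = 0.25  # m/s^2 (and rad/s for the gyroscope channels)
    marker_noise_sd: float = 0.003  # metres
    stance_fraction: float = 0.62
    coordination_offset: tuple[float, float] = (8.0, 6.0)  # % cycle (MA-LA, LA-MA)

    def __post_init__(self) -> None:
        # highest harmonic of the fastest admissible stride (1.5 Hz)
        highest = 1.5 * len(self.harmonic_amplitudes)
        if self.fs_imu <= 2 * highest:
            raise ValueError("fs_imu must exceed twice the highest harmonic frequency")
        if not 0.5 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0.5, 1.0)")
        if self.trial_duration <= 0 or self.n_repeats < 1:
            raise ValueError("trial_duration and n_repeats must be positive")


# ---------------------------------------------------------------------------
# Tabular cohort
# ---------------------------------------------------------------------------


def _sample_population(n: int, spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n participants from the unconstrained population model."""
    m = rng.normal(size=n)  # latent motor severity
    u = LOADING_UPDRS * m + math.sqrt(1 - LOADING_UPDRS**2) * rng.normal(size=n)
    s = LOADING_STRIDE * m + math.sqrt(1 - LOADING_STRIDE**2) * rng.normal(size=n)
    j = LOADING_JERK * m + math.sqrt(1 - LOADING_JERK**2) * rng.normal(size=n)
    a = rng.normal(size=n)  # standardized age component
    sigma = spec.effective_residual_sd()
    z = (
        spec.beta_updrs * u
        + spec.beta_stride * s
        + spec.beta_jerk * j
        - AGE_EFFECT * a
        + sigma * rng.normal(size=n)
    )

    out: dict[str, np.ndarray] = {}
    # demographics
    sex = rng.binomial(1, 0.549, size=n)  # 1 = female
    height = np.where(
        sex == 1, rng.normal(155.5, 6.0, size=n), rng.normal(167.5, 6.0, size=n)
    )
    weight = np.where(
        sex == 1, rng.normal(58.5, 9.0, size=n), rng.normal(69.0, 10.0, size=n)
    )
    pooled_age = _pooled_moments(spec.demographic_params["age"], spec)
    out["demographic__sex"] = sex.astype(float)
    out["demographic__age"] = np.round(pooled_age[0] + pooled_age[1] * a, 1)
    out["demographic__height"] = np.round(height, 1)
    out["demographic__weight"] = np.round(weight, 1)
    out["demographic__bmi"] = np.round(weight / (height / 100.0) ** 2, 2)

    # MoCA and education
    moca = np.clip(np.rint(MOCA_MEAN + MOCA_SD * z), 0, 30).astype(int)
    educ = np.clip(
        np.rint(11.76 + 3.5 * (0.30 * z + math.sqrt(1 - 0.09) * rng.normal(size=n))),
        0,
        22,
    ).astype(int)
    out["clinical__moca"] = moca.astype(float)
    out[schema.EDUCATION_COLUMN] = educ.astype(float)

    # severity-loaded clinical and physical columns
    for col, (mu, sd, lam) in _CLINICAL_PARAMS.items():
        noise = rng.normal(size=n)
        out[col] = mu + sd * (lam * m + math.sqrt(1 - lam**2) * noise)
    out["clinical__hoehn_yahr"] = np.clip(np.rint(out["clinical__hoehn_yahr"] * 2) / 2, 1, 5)
    for col in ("clinical__fall_history", "clinical__nfogq"):
        out[col] = np.clip(np.rint(out[col]), 0, None)

    # gait noise columns (mild severity loadings, plausible scales)
    for task in schema.TASKS:
        factor = _MOCAP_TASK_FACTOR[task]
        for feat in schema.MOCAP_FEATURES:
            mu, sd, lam = _MOCAP_BASE[feat]
            scale = factor if feat in ("Speed", "SLM", "SLL") else 1.0
            col = f"mocap__{task}_{feat}"
            out[col] = mu * scale + sd * max(scale, 0.6) * (
                lam * m + math.sqrt(1 - lam**2) * rng.normal(size=n)
            )
    for feat in schema.MOCAP_COORD_FEATURES:
        mu, sd, lam = _MOCAP_BASE[feat]
        out[f"mocap__FW_{feat}"] = mu + sd * (
            lam * m + math.sqrt(1 - lam**2) * rng.normal(size=n)
        )
    for task in schema.TASKS:
        for placement in schema.PLACEMENTS:
            pf = _PLACEMENT_FACTOR[placement]
            for feat in schema.WEARABLE_FEATURES:
                mu, sd, lam = _WEARABLE_BASE[feat]
                scale = pf if not feat.startswith("SampEn") else 1.0
                col = f"wearable__{task}_{placement}_{feat}"
                out[col] = mu * scale + sd * scale * (
                    lam * m + math.sqrt(1 - lam**2) * rng.normal(size=n)
                )

    # planted driver columns overwrite their noise placeholders
    for col, latent in zip(DRIVER_COLUMNS, (u, s, j)):
        mu, sd = _DRIVER_SCALE[col]
        out[col] = mu + sd * latent
    out["clinical__updrs_iii"] = np.clip(out["clinical__updrs_iii"], 0, 108)
    out["mocap__TurnPS_IMA_SLM"] = np.clip(out["mocap__TurnPS_IMA_SLM"], 0.05, None)
    out["wearable__FW_LANK_MaxJerk"] = np.clip(out["wearable__FW_LANK_MaxJerk"], 1.0, None)

    frame = pd.DataFrame(out)
    frame["_latent_m"] = m
    frame["_latent_z"] = z
    frame["_latent_u"] = u
    frame["_latent_s"] = s
    frame["_latent_j"] = j
    return frame


def _pooled_moments(group_params: Mapping[str, tuple[float, float]], spec: CohortSpec) -> tuple[float, float]:
    wn, wl = spec.n_normal, spec.n_low
    total = wn + wl
    (mn, sn), (ml, sl) = group_params["normal"], group_params["low"]
    mean = (wn * mn + wl * ml) / total
    var = (wn * (sn**2 + (mn - mean) ** 2) + wl * (sl**2 + (ml - mean) ** 2)) / total
    return mean, math.sqrt(var)


def _adjusted_moca(moca: np.ndarray, education: np.ndarray) -> np.ndarray:
    adjusted = moca.astype(int) + (education <= 6).astype(int)
    return np.minimum(adjusted, 30)


def generate_cohort(spec: CohortSpec = CohortSpec()):
    """Generate a cohort with exact group sizes and its latent profiles.

    Returns ``(cohort, profiles)`` where ``cohort`` is a
    :class:`~gaitcog.cohort.CohortTable` (434 candidate columns plus the
    education metadata column, a missingness mask when
    ``spec.missing_rate > 0``, the education-adjusted MoCA outcome and
    the normal/low group label) and ``profiles`` is a list of
    :class:`LatentProfile`, one per participant in row order.

    Group sizes are fixed exactly: draws are assigned to their
    MoCA-defined group until both quotas are filled, so the cohort is a
    group-conditional sample from the population model.
    """
    from .cohort import CohortTable  # local import to avoid a cycle

    rng = rng_from(spec.seed)
    need = {"normal": spec.n_normal, "low": spec.n_low}
    kept: list[pd.DataFrame] = []
    guard = 0
    while need["normal"] > 0 or need["low"] > 0:
        guard += 1
        if guard > 200:
            raise RuntimeError("group quotas not fillable; check the cohort spec")
        batch = _sample_population(2 * (need["normal"] + need["low"]) + 16, spec, rng)
        adjusted = _adjusted_moca(
            batch["clinical__moca"].to_numpy(),
            batch[schema.EDUCATION_COLUMN].to_numpy(),
        )
        labels = np.where(adjusted < 26, "low", "normal")
        for idx in range(len(batch)):
            lab = labels[idx]
            if need[lab] > 0:
                need[lab] -= 1
                kept.append(batch.iloc[[idx]])
            if need["normal"] == 0 and need["low"] == 0:
                break
    table = pd.concat(kept, ignore_index=True)
    ids = [f"P{i + 1:03d}" for i in range(len(table))]
    table.index = pd.Index(ids, name="participant_id")

    adjusted = pd.Series(
        _adjusted_moca(
            table["clinical__moca"].to_numpy(), table[schema.EDUCATION_COLUMN].to_numpy()
        ),
        index=table.index,
        name="moca_adjusted",
    )
    label = pd.Series(
        np.where(adjusted < 26, "low", "normal"), index=table.index, name="label"
    )

    profiles = _build_profiles(table, rng, spec)
    latent_cols = [c for c in table.columns if c.startswith("_latent")]
    data = table.drop(columns=latent_cols)
    data = data[schema.candidate_columns() + [schema.EDUCATION_COLUMN]]

    mask = None
    if spec.missing_rate > 0:
        data, mask = inject_missingness(
            data, spec.missing_rate, seed=int(rng.integers(2**31))
        )
    cohort = CohortTable(data=data, mask=mask, outcome=adjusted, label=label)
    return cohort, profiles


def _build_profiles(
    table: pd.DataFrame, rng: np.random.Generator, spec: CohortSpec
) -> list[LatentProfile]:
    profiles = []
    s_latent = table["_latent_s"].to_numpy()
    j_latent = table["_latent_j"].to_numpy()
    sides = rng.choice(["left", "right"], size=len(table))
    freqs = np.clip(rng.normal(0.9, 0.08, size=len(table)), 0.5, 1.5)
    asym = rng.normal(0.0, 0.02, size=len(table))
    for i, (pid, row) in enumerate(table.iterrows()):
        base = float(np.clip(1.15 + 0.12 * s_latent[i], 0.4, 2.0))
        profiles.append(
            LatentProfile(
                participant_id=str(pid),
                latent_motor_severity=float(row["_latent_m"]),
                latent_cognition=float(row["_latent_z"]),
                more_affected_side=str(sides[i]),
                stride_frequency=float(freqs[i]),
                stride_length_true={
                    "more": base,
                    "less": float(np.clip(base + asym[i] + 0.03, 0.4, 2.0)),
                },
                jerk_scale_true=float(np.exp(0.25 * j_latent[i])),
                seed=int((spec.seed * 1000003 + i) % 2**31),
            )
        )
    return profiles


def inject_missingness(
    table: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set entries missing completely at random, column by column.

    Demographic, outcome (MoCA) and metadata columns are exempt; the
    per-column missing fraction is capped at 5% regardless of the draw.
    Returns the masked copy and the boolean mask (True = missing).
    """
    if not 0 <= rate < 0.05:
        raise ValueError(f"missing rate must lie in [0, 0.05), got {rate}")
    rng = rng_from(seed)
    data = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    if rate == 0:
        return data, mask
    n = len(table)
    cap = int(math.floor(0.05 * n))
    eligible = [
        c
        for c in table.columns
        if schema.category_of(c) in ("clinical", "physical_lifestyle", "mocap", "wearable")
        and c not in schema.COGNITIVE_COLUMNS
    ]
    for col in eligible:
        k = min(int(rng.binomial(n, rate)), cap)
        if k == 0:
            continue
        rows = rng.choice(n, size=k, replace=False)
        data.iloc[rows, data.columns.get_loc(col)] = np.nan
        mask.iloc[rows, mask.columns.get_loc(col)] = True
    return data, mask


# ---------------------------------------------------------------------------
# Raw signals
# ---------------------------------------------------------------------------

_ACC_AXIS_WEIGHT = (1.0, 0.6, 0.8)  # vertical, mediolateral, anteroposterior
_GYR_AXIS_WEIGHT = (0.5, 1.0, 0.7)
# mediolateral gyro harmonics kept fundamental-dominant so each gait
# cycle produces exactly one detection peak
_GYR_Y_HARMONICS = (1.0, 0.3, 0.15)


def _harmonic_series(
    t: np.ndarray,
    freq: float,
    amplitudes: tuple[float, ...],
    phases: np.ndarray,
    scale: float,
) -> np.ndarray:
    out = np.zeros_like(t)
    for k, amp in enumerate(amplitudes, start=1):
        out += amp * np.sin(2 * np.pi * k * freq * t + phases[k - 1])
    return scale * out


def _yaw_profile(t: np.ndarray, duration: float, angle_deg: float, fast: bool) -> np.ndarray:
    """Raised-cosine yaw angular-velocity bump whose time integral is the
    turn angle (in radians)."""
    t_turn = (0.6 if fast else 0.8) * duration
    t0 = 0.5 * (duration - t_turn)
    angle = math.radians(angle_deg)
    peak = 2.0 * angle / t_turn
    inside = (t >= t0) & (t <= t0 + t_turn)
    prof = np.zeros_like(t)
    prof[inside] = 0.5 * peak * (1.0 - np.cos(2 * np.pi * (t[inside] - t0) / t_turn))
    return prof


def generate_imu_trials(
    profile: LatentProfile, spec: SignalSpec = SignalSpec()
) -> list[ImuRecording]:
    """Generate one recording per (placement, task, repeat).

    Each channel is a sum of harmonics of the participant's stride
    frequency with placement-specific amplitudes plus white Gaussian
    noise; turning tasks replace the vertical-axis gyro harmonics with a
    smooth yaw bump integrating to the configured turn angle, and the
    less affected ankle's amplitudes are scaled by ``jerk_scale_true``.
    """
    trials: list[ImuRecording] = []
    n = int(round(spec.trial_duration * spec.fs_imu))
    t = np.arange(n) / spec.fs_imu
    for p_idx, placement in enumerate(schema.PLACEMENTS):
        for t_idx, task in enumerate(schema.TASKS):
            for rep in range(spec.n_repeats):
                rng = np.random.default_rng([profile.seed, p_idx, t_idx, rep])
                acc_scale = PLACEMENT_ACC_SCALE[placement]
                gyr_scale = PLACEMENT_GYR_SCALE[placement]
                if placement == "LANK":
                    acc_scale *= profile.jerk_scale_true
                    gyr_scale *= profile.jerk_scale_true
                is_turn = task.startswith("Turn")
                acc = np.empty((n, 3))
                gyr = np.empty((n, 3))
                for axis in range(3):
                    phases = rng.uniform(0, 2 * np.pi, size=len(spec.harmonic_amplitudes))
                    acc[:, axis] = _harmonic_series(
                        t,
                        profile.stride_frequency,
                        spec.harmonic_amplitudes,
                        phases,
                        acc_scale * _ACC_AXIS_WEIGHT[axis],
                    )
                for axis in range(3):
                    if axis == 1:
                        # fixed phase keeps detection peaks unambiguous
                        phases = np.zeros(len(_GYR_Y_HARMONICS))
                        gyr[:, axis] = _harmonic_series(
                            t,
                            profile.stride_frequency,
                            _GYR_Y_HARMONICS,
                            phases,
                            gyr_scale * _GYR_AXIS_WEIGHT[axis],
                        )
                    elif axis == 0 and is_turn:
                        direction = 1.0 if task.endswith("IMA") else -1.0
                        gyr[:, axis] = direction * _yaw_profile(
                            t, spec.trial_duration, spec.turn_angle, "FS" in task
                        )
                    else:
                        phases = rng.uniform(0, 2 * np.pi, size=len(spec.harmonic_amplitudes))
                        gyr[:, axis] = _harmonic_series(
                            t,
                            profile.stride_frequency,
                            spec.harmonic_amplitudes,
                            phases,
                            gyr_scale * _GYR_AXIS_WEIGHT[axis],
                        )
                if spec.noise_sd > 0:
                    acc = acc + rng.normal(0, spec.noise_sd, size=acc.shape)
                    gyr = gyr + rng.normal(0, spec.noise_sd, size=gyr.shape)
                trials.append(
                    ImuRecording(
                        placement=placement,
                        task=task,
                        repeat_index=rep,
                        fs=spec.fs_imu,
                        acc=acc,
                        gyr=gyr,
                    )
                )
    return trials


_TASK_STRIDE_FACTOR = {
    "FW": 1.0,
    "BW": 0.78,
    "TurnPS_IMA": 0.45,
    "TurnPS_OMA": 0.47,
    "TurnFS_IMA": 0.55,
    "TurnFS_OMA": 0.57,
}


def _heel_trajectory(
    t: np.ndarray,
    contacts: np.ndarray,
    positions: np.ndarray,
    stance_fraction: float,
    cycle: float,
) -> np.ndarray:
    """Heel forward position: stationary in stance, half-cosine advance in swing."""
    x = np.full_like(t, positions[0])
    for k in range(len(contacts) - 1):
        c0, c1 = contacts[k], contacts[k + 1]
        p0, p1 = positions[k], positions[k + 1]
        off = c0 + stance_fraction * cycle
        x[(t >= c0) & (t < off)] = p0
        swing = (t >= off) & (t < c1)
        if np.any(swing):
            phase = (t[swing] - off) / (c1 - off)
            x[swing] = p0 + (p1 - p0) * 0.5 * (1 - np.cos(np.pi * phase))
        x[t >= c1] = p1
    return x


def generate_mocap_trial(
    profile: LatentProfile,
    spec: SignalSpec = SignalSpec(),
    task: str = "FW",
    repeat_index: int = 0,
) -> MocapTrial:
    """Generate one simplified marker trial with its foot-event schedule."""
    if task not in schema.TASKS:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng([profile.seed, 977, schema.TASKS.index(task), repeat_index])
    f = profile.stride_frequency
    cycle = 1.0 / f
    n = int(round(spec.trial_duration * spec.fs_mocap))
    t = np.arange(n) / spec.fs_mocap
    factor = _TASK_STRIDE_FACTOR[task]
    sl = {side: factor * profile.stride_length_true[side] for side in ("more", "less")}

    contacts: dict[str, np.ndarray] = {}
    foot_offs: dict[str, np.ndarray] = {}
    contact_positions: dict[str, np.ndarray] = {}
    for side, offset in (("more", 0.0), ("less", 0.5 * cycle)):
        times = np.arange(offset, spec.trial_duration - 0.5 * cycle, cycle)
        pos = sl[side] * np.arange(len(times)) + (0.5 * sl[side] if side == "less" else 0.0)
        if spec.marker_noise_sd > 0:
            pos = pos + rng.normal(0, spec.marker_noise_sd, size=pos.shape)
        contacts[side] = times
        foot_offs[side] = times + spec.stance_fraction * cycle
        contact_positions[side] = pos

    speed = 0.5 * (sl["more"] + sl["less"]) * f
    pelvis = np.column_stack([speed * t, np.zeros(n), np.full(n, 0.94)])
    heel_more = np.column_stack(
        [
            _heel_trajectory(t, contacts["more"], contact_positions["more"], spec.stance_fraction, cycle),
            np.full(n, -0.09),
            np.zeros(n),
        ]
    )
    heel_less = np.column_stack(
        [
            _heel_trajectory(t, contacts["less"], contact_positions["less"], spec.stance_fraction, cycle),
            np.full(n, 0.09),
            np.zeros(n),
        ]
    )
    if spec.marker_noise_sd > 0:
        pelvis = pelvis + rng.normal(0, spec.marker_noise_sd, size=pelvis.shape)
        heel_more = heel_more + rng.normal(0, spec.marker_noise_sd, size=heel_more.shape)
        heel_less = heel_less + rng.normal(0, spec.marker_noise_sd, size=heel_less.shape)

    off_mala = spec.coordination_offset[0] / 100.0 * cycle
    off_lama = spec.coordination_offset[1] / 100.0 * cycle
    angles = {
        "elbow_more": np.sin(2 * np.pi * f * t),
        "knee_less": np.sin(2 * np.pi * f * (t - off_mala)),
        "elbow_less": np.sin(2 * np.pi * f * t + np.pi),
        "knee_more": np.sin(2 * np.pi * f * (t - off_lama) + np.pi),
    }
    return MocapTrial(
        task=task,
        repeat_index=repeat_index,
        fs=spec.fs_mocap,
        t=t,
        markers={"pelvis": pelvis, "heel_more": heel_more, "heel_less": heel_less},
        angles=angles,
        contacts=contacts,
        foot_offs=foot_offs,
        contact_positions=contact_positions,
        stance_fraction=spec.stance_fraction,
    )


def generate_mocap_trials(
    profile: LatentProfile, spec: SignalSpec = SignalSpec()
) -> list[MocapTrial]:
    return [
        generate_mocap_trial(profile, spec, task=task, repeat_index=rep)
        for task in schema.TASKS
        for rep in range(spec.n_repeats)
    ]


# ---------------------------------------------------------------------------
# Planted binary test-bed
# ---------------------------------------------------------------------------


def make_planted_binary_cohort(
    n_per_class: tuple[int, int] = (60, 42),
    n_informative: int = 5,
    n_noise: int = 25,
    effect: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Small two-class feature table with a known informative subset.

    The first ``n_informative`` columns are shifted between classes by
    ``effect`` standard deviations; the rest are pure noise.  Used as a
    ground-truthed test bed for feature-selection stability and
    classifier calibration checks.
    """
    rng = rng_from(seed)
    n0, n1 = n_per_class
    n = n0 + n1
    y = np.array([0] * n0 + [1] * n1)
    X = rng.normal(size=(n, n_informative + n_noise))
    X[y == 1, :n_informative] += effect
    cols = [f"signal_{i}" for i in range(n_informative)] + [
        f"noise_{i}" for i in range(n_noise)
    ]
    idx = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="participant_id")
    frame = pd.DataFrame(X, columns=cols, index=idx)
    labels = pd.Series(np.where(y == 1, "low", "normal"), index=idx, name="label")
    return frame, labels
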