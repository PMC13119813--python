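"""Gait feature extraction from raw wearable-sensor and marker signals.

This module turns one trial's raw signals into the participant-level
gait features used downstream:

* ten wearable-sensor features per (placement, task): peak jerk and peak
  angular jerk (movement-smoothness metrics), mean / max / RMS of the
  Euclidean magnitude of acceleration and angular velocity, and the
  sample entropy of both magnitude series;
* spatiotemporal parameters from simplified marker trajectories: walking
  speed, per-side stride length, single/double-support percentages and
  contralateral elbow-knee timing coordination.

Signals are low-pass filtered with a zero-lag (forward-backward)
Butterworth filter and segmented into gait cycles before any feature is
computed, so that turn-initiation and stopping transients do not
contaminate peak-based features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

log = logging.getLogger(__name__)

__all__ = [
    "ImuRecording",
    "MocapTrial",
    "FilterSpec",
    "GaitEvents",
    "SampleEntropySpec",
    "SampleEntropyResult",
    "WearableFeatures",
    "SpatioTemporal",
    "CycleDetectionError",
    "lowpass_filter",
    "detect_gait_cycles",
    "magnitude",
    "max_jerk",
    "max_angular_jerk",
    "signal_stats",
    "sample_entropy",
    "extract_wearable_features",
    "extract_spatiotemporal",
]


class CycleDetectionError(RuntimeError):
    """Raised when a trial shows no usable gait periodicity."""


@dataclass(frozen=True)
class ImuRecording:
    """One sensor placement x task condition x repeat.

    ``acc`` and ``gyr`` are (n, 3) arrays; axes are x vertical,
    y mediolateral, z anteroposterior.
    """

    placement: str
    task: str
    repeat_index: int
    fs: float
    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        acc = np.asarray(self.acc, dtype=float)
        gyr = np.asarray(self.gyr, dtype=float)
        if acc.ndim != 2 or acc.shape[1] != 3 or gyr.shape != acc.shape:
            raise ValueError("acc and gyr must be equal-length (n, 3) arrays")
        if acc.shape[0] < 3 * self.fs:
            raise ValueError("recording shorter than 3 s of samples")
        if not (np.isfinite(acc).all() and np.isfinite(gyr).all()):
            raise ValueError("recording contains non-finite samples")
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyr", gyr)

    @property
    def n_samples(self) -> int:
        return int(self.acc.shape[0])


@dataclass(frozen=True)
class MocapTrial:
    """Simplified marker-trajectory trial.

    markers maps marker name -> (n, 3) position series in metres with x
    the direction of progression; angles maps joint name ('elbow_more',
    'elbow_less', 'knee_more', 'knee_less') -> flexion angle series.
    ``contacts`` holds per-side foot-contact times (s) and ``foot_offs``
    the corresponding end-of-stance times.
    """

    task: str
    repeat_index: int
    fs: float
    t: np.ndarray
    markers: Mapping[str, np.ndarray]
    angles: Mapping[str, np.ndarray]
    contacts: Mapping[str, np.ndarray]
    foot_offs: Mapping[str, np.ndarray]
    contact_positions: Mapping[str, np.ndarray]
    stance_fraction: float


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag low-pass Butterworth filter parameters.

    The cutoff default (12 Hz for 60 Hz IMU data) preserves the gait
    harmonics (< 10 Hz) while suppressing wideband sensor noise; marker
    data conventionally use 6 Hz.
    """

    order: int = 4
    cutoff: float = 12.0
    zero_lag: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.cutoff < fs / 2:
            raise ValueError(
                f"cutoff must lie in (0, fs/2)=(0, {fs / 2}), got {self.cutoff}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


MOCAP_FILTER = FilterSpec(order=4, cutoff=6.0)


@dataclass(frozen=True)
class GaitEvents:
    """Cycle boundaries (sample indices) and optional per-side stance intervals."""

    cycle_boundaries: np.ndarray
    stance_intervals: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.cycle_boundaries, dtype=int)
        if b.size < 3 or np.any(np.diff(b) <= 0):
            raise ValueError(
                "cycle_boundaries must be strictly increasing and span >= 2 cycles"
            )
        object.__setattr__(self, "cycle_boundaries", b)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_boundaries.size - 1)

    @property
    def segment(self) -> tuple[int, int]:
        return int(self.cycle_boundaries[0]), int(self.cycle_boundaries[-1])


@dataclass(frozen=True)
class SampleEntropySpec:
    """Template length m and tolerance factor (r = r_factor * SD)."""

    m: int = 2
    r_factor: float = 0.2


@dataclass(frozen=True)
class SampleEntropyResult:
    value: float  # nats; NaN when undefined (A == 0 or B == 0)
    a_count: int  # matched (m+1)-template pairs
    b_count: int  # matched m-template pairs

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass(frozen=True)
class WearableFeatures:
    """The ten wearable-sensor features for one (placement, task, repeat)."""

    max_jerk: float
    max_angular_jerk: float
    mean_acc: float
    max_acc: float
    rms_acc: float
    mean_gyr: float
    max_gyr: float
    rms_gyr: float
    sampen_acc: float
    sampen_gyr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MaxJerk": self.max_jerk,
            "MaxAngJerk": self.max_angular_jerk,
            "MeanAcc": self.mean_acc,
            "MaxAcc": self.max_acc,
            "RMSAcc": self.rms_acc,
            "MeanGyr": self.mean_gyr,
            "MaxGyr": self.max_gyr,
            "RMSGyr": self.rms_gyr,
            "SampEnAcc": self.sampen_acc,
            "SampEnGyr": self.sampen_gyr,
        }


@dataclass(frozen=True)
class SpatioTemporal:
    walking_speed: float  # m/s
    stride_length_more: float  # m
    stride_length_less: float  # m
    single_support_more: float  # % cycle
    single_support_less: float  # % cycle
    double_support: float  # % cycle
    coord_ma_la: float  # % cycle, more-affected elbow vs less-affected knee
    coord_la_ma: float  # % cycle, less-affected elbow vs more-affected knee

    def as_dict(self) -> dict[str, float]:
        return {
            "Speed": self.walking_speed,
            "SLM": self.stride_length_more,
            "SLL": self.stride_length_less,
            "SSM": self.single_support_more,
            "SSL": self.single_support_less,
            "DS": self.double_support,
            "CoordMALA": self.coord_ma_la,
            "CoordLAMA": self.coord_la_ma,
        }


# ---------------------------------------------------------------------------
# Filtering and basic signal operations
# ---------------------------------------------------------------------------


def lowpass_filter(
    series: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter along the first axis.

    Forward-backward filtering (``filtfilt``) doubles the effective
    order's attenuation and cancels phase delay, so peak locations are
    preserved.  Output length equals input length.
    """
    spec.validate(fs)
    x = np.asarray(series, dtype=float)
    min_len = 3 * (spec.order + 1)
    if x.shape[0] <= min_len:
        raise ValueError(f"series too short to filter ({x.shape[0]} <= {min_len})")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.zero_lag:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def magnitude(tri: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a triaxial (n, 3) series."""
    x = np.asarray(tri, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in triaxial series")
    return np.sqrt(np.sum(x * x, axis=-1))


def _first_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # central differences, one-sided at the ends (np.gradient convention);
    # exact for polynomials of degree <= 1 everywhere, degree <= 2 interior
    return np.gradient(x, 1.0 / fs, axis=0)


def _second_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # second central difference in the interior; the end samples copy the
    # adjacent one-sided second difference, which is exact on quadratics
    dt2 = (1.0 / fs) ** 2
    out = np.empty_like(x, dtype=float)
    out[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt2
    out[0] = (x[2] - 2.0 * x[1] + x[0]) / dt2
    out[-1] = (x[-1] - 2.0 * x[-2] + x[-3]) / dt2
    return out


def max_jerk(acc: np.ndarray, fs: float) -> float:
    """Peak jerk magnitude (m/s^3): norm of the per-axis first derivative."""
    a = np.atleast_2d(np.asarray(acc, dtype=float))
    if a.shape[0] < 2:
        raise ValueError("max_jerk needs at least 2 samples")
    jerk = _first_derivative(a, fs)
    return float(np.max(magnitude(jerk)))


def max_angular_jerk(gyr: np.ndarray, fs: float) -> float:
    """Peak angular jerk magnitude (rad/s^3): norm of the second derivative."""
    g = np.atleast_2d(np.asarray(gyr, dtype=float))
    if g.shape[0] < 3:
        raise ValueError("max_angular_jerk needs at least 3 samples")
    ang_jerk = _second_derivative(g, fs)
    return float(np.max(magnitude(ang_jerk)))


def signal_stats(tri: np.ndarray) -> dict[str, float]:
    """Mean, max and RMS of the magnitude of a triaxial series."""
    mag = magnitude(np.atleast_2d(np.asarray(tri, dtype=float)))
    if mag.size == 0:
        raise ValueError("empty series")
    return {
        "mean": float(np.mean(mag)),
        "max": float(np.max(mag)),
        "rms": float(np.sqrt(np.mean(mag * mag))),
    }


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------


def sample_entropy(
    series: np.ndarray, spec: SampleEntropySpec = SampleEntropySpec()
) -> SampleEntropyResult:
    """Sample entropy -ln(A/B) with Chebyshev tolerance r = r_factor * SD.

    Templates of length m are the n-m windows ``x[i:i+m]`` for
    i = 0..n-m-1 (the same index range is used for the (m+1)-templates,
    following the standard Richman-Moorman counting); B counts template
    pairs i < j whose Chebyshev distance is <= r, A the same for length
    m+1.  A constant series is defined to have entropy 0 (all templates
    match at tolerance 0); if A or B is zero the value is undefined and
    reported as NaN so it can flow into imputation downstream.
    """
    x = np.asarray(series, dtype=float).ravel()
    m = int(spec.m)
    n = x.size
    if m < 1:
        raise ValueError("template length m must be >= 1")
    if n < m + 2:
        raise ValueError(f"series too short for sample entropy (n={n}, m={m})")
    sd = float(np.std(x))
    n_templates = n - m
    if sd == 0.0:
        n_pairs = n_templates * (n_templates - 1) // 2
        return SampleEntropyResult(0.0, n_pairs, n_pairs)
    r = spec.r_factor * sd

    # Chebyshev distances between windows, built incrementally: the
    # distance between length-k templates is the running max over the k
    # per-offset |x_i - x_j| matrices.
    windows_m1 = sliding_window_view(x, m + 1)[:n_templates]  # (n-m, m+1)
    d = np.abs(windows_m1[:, None, :] - windows_m1[None, :, :])  # (N, N, m+1)
    cheb_m = d[:, :, :m].max(axis=2)
    cheb_m1 = np.maximum(cheb_m, d[:, :, m])
    iu = np.triu_indices(n_templates, k=1)
    b_count = int(np.count_nonzero(cheb_m[iu] <= r))
    a_count = int(np.count_nonzero(cheb_m1[iu] <= r))
    if a_count == 0 or b_count == 0:
        return SampleEntropyResult(float("nan"), a_count, b_count)
    return SampleEntropyResult(-math.log(a_count / b_count), a_count, b_count)


# ---------------------------------------------------------------------------
# Gait events
# ---------------------------------------------------------------------------


def detect_gait_cycles(
    recording: ImuRecording,
    filter_spec: FilterSpec = FilterSpec(),
    min_cycle_s: float = 0.4,
    max_spacing_cv: float = 0.30,
    min_period_autocorr: float = 0.4,
) -> GaitEvents:
    """Segment a recording into gait cycles.

    Cycle boundaries are successive same-sign peaks of the mediolateral
    angular velocity (the dominant stride-periodic channel at the
    ankle), picked with a minimum spacing of ``min_cycle_s`` and a
    prominence threshold tied to the channel's spread.  A trial is
    flagged as undetectable when it yields fewer than two cycles, when
    the peak spacing is too irregular (coefficient of variation above
    ``max_spacing_cv``), or when the signal's autocorrelation at the
    candidate period falls below ``min_period_autocorr`` (band-limited
    noise can produce regularly spaced peaks, but never a strong
    period-lag autocorrelation).
    """
    gy = lowpass_filter(recording.gyr, recording.fs, filter_spec)[:, 1]
    prominence = 0.5 * float(np.std(gy))
    if prominence <= 0:
        raise CycleDetectionError("flat mediolateral angular velocity")
    peaks, _ = sps.find_peaks(
        gy, distance=max(1, int(round(min_cycle_s * recording.fs))), prominence=prominence
    )
    if peaks.size < 3:
        raise CycleDetectionError(
            f"only {peaks.size} candidate cycle boundaries detected"
        )
    spacing = np.diff(peaks)
    cv = float(np.std(spacing) / np.mean(spacing))
    lag = int(np.median(spacing))
    centered = gy - gy.mean()
    denom = float(centered @ centered)
    ac = float(centered[:-lag] @ centered[lag:] / denom) if denom > 0 else 0.0
    if cv > max_spacing_cv or ac < min_period_autocorr:
        log.warning(
            "trial %s/%s/%d flagged: spacing CV=%.2f, period autocorr=%.2f",
            recording.placement,
            recording.task,
            recording.repeat_index,
            cv,
            ac,
        )
        raise CycleDetectionError(
            f"no stable periodicity (spacing CV={cv:.2f}, autocorr={ac:.2f})"
        )
    return GaitEvents(cycle_boundaries=peaks)


# ---------------------------------------------------------------------------
# Wearable feature extraction
# ---------------------------------------------------------------------------


def extract_wearable_features(
    recording: ImuRecording,
    events: GaitEvents,
    sampen_spec: SampleEntropySpec = SampleEntropySpec(),
    filter_spec: FilterSpec = FilterSpec(),
) -> WearableFeatures:
    """Compute the ten wearable features on the cycle-segmented signals.

    Filtering is applied to the full trial (the zero-lag filter needs
    context on both sides), then all features are evaluated strictly on
    the region between the first and last cycle boundary.
    """
    lo, hi = events.segment
    if hi > recording.n_samples:
        raise ValueError("events extend past the end of the recording")
    acc = lowpass_filter(recording.acc, recording.fs, filter_spec)[lo:hi]
    gyr = lowpass_filter(recording.gyr, recording.fs, filter_spec)[lo:hi]
    acc_stats = signal_stats(acc)
    gyr_stats = signal_stats(gyr)
    sampen_acc = sample_entropy(magnitude(acc), sampen_spec)
    sampen_gyr = sample_entropy(magnitude(gyr), sampen_spec)
    return WearableFeatures(
        max_jerk=max_jerk(acc, recording.fs),
        max_angular_jerk=max_angular_jerk(gyr, recording.fs),
        mean_acc=acc_stats["mean"],
        max_acc=acc_stats["max"],
        rms_acc=acc_stats["rms"],
        mean_gyr=gyr_stats["mean"],
        max_gyr=gyr_stats["max"],
        rms_gyr=gyr_stats["rms"],
        sampen_acc=sampen_acc.value,
        sampen_gyr=sampen_gyr.value,
    )


# ---------------------------------------------------------------------------
# Spatiotemporal extraction from marker trajectories
# ---------------------------------------------------------------------------


def _mean_stride_length(positions: np.ndarray) -> float:
    # consecutive ipsilateral contact positions in the horizontal plane
    steps = np.diff(positions[:, :2] if positions.ndim == 2 else positions, axis=0)
    if steps.ndim == 1:
        return float(np.mean(np.abs(steps)))
    return float(np.mean(np.linalg.norm(steps, axis=1)))


def _support_phases(
    contacts: Mapping[str, np.ndarray], foot_offs: Mapping[str, np.ndarray]
) -> tuple[float, float, float]:
    """Single-support per side and total double support, in % of cycle.

    Derived from the event schedule: over the analysis window the time
    both feet are on the ground is double support; the time only one
    foot is down is that side's *contralateral* swing, i.e. single
    support of the stance side.
    """
    events = []
    for side in ("more", "less"):
        for t in np.asarray(contacts[side], dtype=float):
            events.append((t, side, 1))
        for t in np.asarray(foot_offs[side], dtype=float):
            events.append((t, side, 0))
    events.sort()
    t0 = max(np.min(contacts["more"]), np.min(contacts["less"]))
    t1 = min(np.max(contacts["more"]), np.max(contacts["less"]))
    if t1 <= t0:
        raise ValueError("contact schedules do not overlap")
    # state per side at t0
    down = {}
    for side in ("more", "less"):
        c = np.asarray(contacts[side], dtype=float)
        f = np.asarray(foot_offs[side], dtype=float)
        last_c = c[c <= t0].max(initial=-np.inf)
        last_f = f[f <= t0].max(initial=-np.inf)
        down[side] = last_c >= last_f
    durations = {"double": 0.0, "single_more": 0.0, "single_less": 0.0}
    prev = t0
    for t, side, state in events:
        if t <= t0 or t > t1:
            if t > t1:
                break
            continue
        span = t - prev
        if down["more"] and down["less"]:
            durations["double"] += span
        elif down["more"]:
            durations["single_more"] += span
        elif down["less"]:
            durations["single_less"] += span
        down[side] = bool(state)
        prev = t
    span = t1 - prev
    if down["more"] and down["less"]:
        durations["double"] += span
    elif down["more"]:
        durations["single_more"] += span
    elif down["less"]:
        durations["single_less"] += span
    total = t1 - t0
    return (
        100.0 * durations["single_more"] / total,
        100.0 * durations["single_less"] / total,
        100.0 * durations["double"] / total,
    )


def _coordination(
    t: np.ndarray,
    elbow: np.ndarray,
    knee: np.ndarray,
    cycle_duration: float,
    fs: float,
) -> float:
    """Mean timing difference between elbow and contralateral knee flexion
    peaks, expressed in % of the gait cycle (wrapped to [0, 50])."""
    min_dist = max(1, int(round(0.5 * cycle_duration * fs)))
    pe, _ = sps.find_peaks(elbow, distance=min_dist)
    pk, _ = sps.find_peaks(knee, distance=min_dist)
    if pe.size == 0 or pk.size == 0:
        return float("nan")
    te, tk = t[pe], t[pk]
    diffs = []
    for ts in te:
        nearest = tk[np.argmin(np.abs(tk - ts))]
        frac = abs(nearest - ts) / cycle_duration
        frac = frac % 1.0
        diffs.append(min(frac, 1.0 - frac) * 100.0)
    return float(np.mean(diffs))


def extract_spatiotemporal(trial: MocapTrial) -> SpatioTemporal:
    """Spatiotemporal gait parameters from a marker trial and its event schedule."""
    for side in ("more", "less"):
        if np.asarray(trial.contacts[side]).size < 2:
            raise ValueError(f"need >= 2 ipsilateral contacts on the {side} side")
    sl_more = _mean_stride_length(np.asarray(trial.contact_positions["more"]))
    sl_less = _mean_stride_length(np.asarray(trial.contact_positions["less"]))
    pelvis = np.asarray(trial.markers["pelvis"], dtype=float)
    path = float(np.sum(np.linalg.norm(np.diff(pelvis[:, :2], axis=0), axis=1)))
    duration = float(trial.t[-1] - trial.t[0])
    speed = path / duration
    ss_more, ss_less, ds = _support_phases(trial.contacts, trial.foot_offs)
    cycle = float(np.mean(np.diff(np.asarray(trial.contacts["more"], dtype=float))))
    coord_ma_la = _coordination(
        trial.t, trial.angles["elbow_more"], trial.angles["knee_less"], cycle, trial.fs
    )
    coord_la_ma = _coordination(
        trial.t, trial.angles["elbow_less"], trial.angles["knee_more"], cycle, trial.fs
    )
    return SpatioTemporal(
        walking_speed=speed,
        stride_length_more=sl_more,
        stride_length_less=sl_less,
        single_support_more=ss_more,
        single_support_less=ss_less,
        double_support=ds,
        coord_ma_la=coord_ma_la,
        coord_la_ma=coord_la_ma,
    )
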