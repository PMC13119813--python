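import numpy as np
import pytest

from gaitcog.simulate import CohortSpec, LatentProfile, SignalSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (60 normal / 42 low-MoCA), shared
    read-only across tests."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def profile():
    return LatentProfile(
        participant_id="P001",
        latent_motor_severity=0.0,
        latent_cognition=0.0,
        more_affected_side="left",
        stride_frequency=1.0,
        stride_length_true={"more": 1.2, "less": 1.2},
        jerk_scale_true=1.0,
        seed=11,
    )


@pytest.fixture()
def quiet_signal_spec():
    return SignalSpec(noise_sd=0.0, marker_noise_sd=0.0)


def sampen_bruteforce(x, m=2, r_factor=0.2):
    """O(n^2) template-counting oracle for sample entropy.

    Counts pairs i < j over the n-m templates (the same index range for
    both template lengths), Chebyshev distance, r = r_factor * SD.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x))
    if sd == 0.0:
        n_pairs = (n - m) * (n - m - 1) // 2
        return 0.0, n_pairs, n_pairs
    r = r_factor * sd
    big_n = n - m
    a = b = 0
    for i in range(big_n):
        for j in range(i + 1, big_n):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan"), a, b
    return float(-np.log(a / b)), a, b


def knn_impute_bruteforce(values, k):
    """Exhaustive-search oracle for kNN imputation.

    Standardizes with nan-aware moments, computes the nan-aware
    Euclidean distance sqrt(n_cols / n_shared * sum_shared (x-y)^2), and
    replaces each missing cell with the mean over the k nearest rows
    that observe the feature (all available donors when fewer than k).
    """
    X = np.array(values, dtype=float)
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    out = Z.copy()
    for i in range(n):
        for j in range(p):
            if not np.isnan(Z[i, j]):
                continue
            dists = np.full(n, np.inf)
            for other in range(n):
                if other == i or np.isnan(Z[other, j]):
                    continue
                shared = ~(np.isnan(Z[i]) | np.isnan(Z[other]))
                if shared.sum() == 0:
                    continue
                diff = Z[i, shared] - Z[other, shared]
                dists[other] = np.sqrt(p / shared.sum() * np.sum(diff**2))
            order = np.argsort(dists, kind="stable")
            donors = [o for o in order if np.isfinite(dists[o])][:k]
            out[i, j] = np.mean([Z[o, j] for o in donors])
    return out * sd + mu
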