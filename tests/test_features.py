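"""Signal-processing operations against analytic and brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitcog.features import (
    CycleDetectionError,
    FilterSpec,
    GaitEvents,
    ImuRecording,
    SampleEntropySpec,
    detect_gait_cycles,
    extract_spatiotemporal,
    extract_wearable_features,
    lowpass_filter,
    magnitude,
    max_angular_jerk,
    max_jerk,
    sample_entropy,
    signal_stats,
)
from gaitcog.simulate import SignalSpec, generate_imu_trials, generate_mocap_trial

from conftest import sampen_bruteforce

FS = 60.0


def _recording(acc, gyr, placement="MANK", task="FW"):
    return ImuRecording(
        placement=placement, task=task, repeat_index=0, fs=FS, acc=acc, gyr=gyr
    )


class TestLowpassFilter:
    def test_constant_series_passes_unchanged(self):
        x = np.full(300, 2.5)
        y = lowpass_filter(x, FS, FilterSpec(cutoff=12.0))
        np.testing.assert_allclose(y[50:-50], 2.5, atol=1e-9)

    def test_tone_attenuation_matches_analytic_response(self):
        # forward-backward filtering applies the squared magnitude
        # response; the digital Butterworth's response is the analog
        # formula evaluated at bilinear-warped frequencies tan(pi f/fs)
        f_tone, cutoff, order = 25.0, 12.0, 4
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * f_tone * t)
        y = lowpass_filter(x, FS, FilterSpec(order=order, cutoff=cutoff))
        core = slice(300, -300)  # ignore edge transients
        ratio = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        warped = math.tan(math.pi * f_tone / FS) / math.tan(math.pi * cutoff / FS)
        analytic = (1.0 / math.sqrt(1.0 + warped ** (2 * order))) ** 2
        assert ratio == pytest.approx(analytic, rel=0.05)

    def test_zero_phase_preserves_pulse_peak(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.exp(-0.5 * ((t - 5.0) / 0.5) ** 2)
        y = lowpass_filter(x, FS, FilterSpec(cutoff=6.0))
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_filter(np.ones(10), FS, FilterSpec())


class TestMagnitudeAndStats:
    def test_three_four_five(self):
        tri = np.tile([3.0, 4.0, 0.0], (20, 1))
        np.testing.assert_allclose(magnitude(tri), 5.0)
        stats = signal_stats(tri)
        assert stats == {"mean": 5.0, "max": 5.0, "rms": 5.0}

    def test_zero_vector(self):
        assert magnitude(np.zeros((5, 3))).max() == 0.0

    def test_rotating_unit_vector_has_unit_norm(self):
        th = np.linspace(0, 4 * np.pi, 100)
        tri = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        np.testing.assert_allclose(magnitude(tri), 1.0, atol=1e-12)

    def test_alternating_magnitudes(self):
        tri = np.zeros((10, 3))
        tri[1::2, 0] = 2.0
        stats = signal_stats(tri)
        assert stats["mean"] == pytest.approx(1.0)
        assert stats["max"] == pytest.approx(2.0)
        assert stats["rms"] == pytest.approx(math.sqrt(2.0))

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_power_mean_ordering(self, rows):
        stats = signal_stats(np.array(rows))
        assert stats["mean"] <= stats["rms"] + 1e-9
        assert stats["rms"] <= stats["max"] + 1e-9


class TestJerk:
    def test_constant_acceleration_has_zero_jerk(self):
        acc = np.tile([1.0, -2.0, 0.5], (50, 1))
        assert max_jerk(acc, FS) == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_is_exact(self):
        t = np.arange(120) / FS
        acc = np.column_stack([np.zeros_like(t), np.zeros_like(t), 2.0 * t])
        assert max_jerk(acc, FS) == pytest.approx(2.0, rel=1e-12)

    def test_sinusoid_matches_analytic_peak_derivative(self):
        f = 2.0
        t = np.arange(0, 10, 1 / FS)
        acc = np.column_stack([np.sin(2 * np.pi * f * t), np.zeros_like(t), np.zeros_like(t)])
        assert max_jerk(acc, FS) == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_constant_angular_velocity_zero(self):
        gyr = np.tile([0.3, 0.3, 0.3], (50, 1))
        assert max_angular_jerk(gyr, FS) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_angular_velocity_exact(self):
        # second central difference is exact on polynomials of degree <= 2
        b = 3.0
        t = np.arange(120) / FS
        gyr = np.column_stack([np.zeros_like(t), 0.5 * b * t**2, np.zeros_like(t)])
        assert max_angular_jerk(gyr, FS) == pytest.approx(b, rel=1e-9)

    def test_sinusoidal_angular_velocity_matches_analytic(self):
        f = 1.0
        t = np.arange(0, 10, 1 / FS)
        gyr = np.column_stack([np.zeros_like(t), np.sin(2 * np.pi * f * t), np.zeros_like(t)])
        assert max_angular_jerk(gyr, FS) == pytest.approx((2 * np.pi * f) ** 2, rel=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            max_jerk(np.zeros((1, 3)), FS)
        with pytest.raises(ValueError):
            max_angular_jerk(np.zeros((2, 3)), FS)


class TestSampleEntropy:
    def test_constant_series_is_zero_by_convention(self):
        res = sample_entropy(np.full(50, 3.3))
        assert res.value == 0.0
        assert res.a_count == res.b_count > 0

    def test_matches_bruteforce_on_small_ramp(self):
        x = np.arange(1.0, 11.0)
        res = sample_entropy(x)
        val, a, b = sampen_bruteforce(x)
        assert (res.a_count, res.b_count) == (a, b)
        if math.isnan(val):
            assert math.isnan(res.value)
        else:
            assert res.value == pytest.approx(val, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        kind = seed % 3
        if kind == 0:
            x = rng.normal(size=n)
        elif kind == 1:
            x = np.sin(np.arange(n) * 0.3) + 0.1 * rng.normal(size=n)
        else:
            x = np.round(rng.normal(size=n), 1)  # ties stress the tolerance
        res = sample_entropy(x)
        val, a, b = sampen_bruteforce(x)
        assert (res.a_count, res.b_count) == (a, b)
        if math.isnan(val):
            assert math.isnan(res.value)
        else:
            assert res.value == pytest.approx(val, abs=1e-12)

    def test_counts_ordered(self):
        rng = np.random.default_rng(0)
        res = sample_entropy(rng.normal(size=200))
        assert res.a_count <= res.b_count
        assert res.value >= 0.0

    def test_white_noise_more_irregular_than_sinusoid(self):
        rng = np.random.default_rng(42)
        t = np.arange(500) / 60.0
        sine = np.sin(2 * np.pi * 1.0 * t)
        noise_vals, sine_vals = [], []
        for _ in range(30):
            noise_vals.append(sample_entropy(rng.normal(size=500)).value)
            jitter = sine + 1e-6 * rng.normal(size=500)
            sine_vals.append(sample_entropy(jitter).value)
        assert np.nanmean(noise_vals) > np.nanmean(sine_vals)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0))


class TestCycleDetection:
    def _noiseless_trial(self, profile_seed=11, duration=10.0):
        from gaitcog.simulate import LatentProfile

        profile = LatentProfile(
            participant_id="T",
            latent_motor_severity=0.0,
            latent_cognition=0.0,
            more_affected_side="left",
            stride_frequency=1.0,
            stride_length_true={"more": 1.2, "less": 1.2},
            jerk_scale_true=1.0,
            seed=profile_seed,
        )
        spec = SignalSpec(noise_sd=0.0, marker_noise_sd=0.0, trial_duration=duration)
        trials = generate_imu_trials(profile, spec)
        return next(
            t for t in trials
            if t.placement == "MANK" and t.task == "FW" and t.repeat_index == 0
        )

    def test_noiseless_trial_yields_expected_cycles(self):
        rec = self._noiseless_trial()
        events = detect_gait_cycles(rec)
        assert 9 <= events.n_cycles <= 10
        spacing = np.diff(events.cycle_boundaries)
        assert np.all(np.abs(spacing - 60) <= 2)

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(1)
        rec = _recording(rng.normal(size=(600, 3)), rng.normal(size=(600, 3)))
        with pytest.raises(CycleDetectionError):
            detect_gait_cycles(rec)

    def test_amplitude_invariance(self):
        rec = self._noiseless_trial()
        scaled = _recording(2.0 * rec.acc, 2.0 * rec.gyr)
        e1 = detect_gait_cycles(rec)
        e2 = detect_gait_cycles(scaled)
        np.testing.assert_array_equal(e1.cycle_boundaries, e2.cycle_boundaries)


class TestExtractWearable:
    def _trial_and_events(self):
        det = TestCycleDetection()
        rec = det._noiseless_trial()
        return rec, detect_gait_cycles(rec)

    def test_exactly_ten_features(self):
        rec, events = self._trial_and_events()
        feats = extract_wearable_features(rec, events)
        assert len(feats.as_dict()) == 10
        assert feats.max_acc >= feats.mean_acc > 0
        assert feats.max_gyr >= feats.mean_gyr >= 0
        assert feats.rms_acc <= feats.max_acc

    def test_amplitude_scale_equivariance(self):
        rec, events = self._trial_and_events()
        doubled = _recording(2.0 * rec.acc, 2.0 * rec.gyr)
        f1 = extract_wearable_features(rec, events).as_dict()
        f2 = extract_wearable_features(doubled, events).as_dict()
        for key in ("MaxJerk", "MaxAngJerk", "MeanAcc", "MaxAcc", "RMSAcc",
                    "MeanGyr", "MaxGyr", "RMSGyr"):
            assert f2[key] == pytest.approx(2.0 * f1[key], rel=1e-9)
        for key in ("SampEnAcc", "SampEnGyr"):
            assert f2[key] == pytest.approx(f1[key], abs=1e-6)

    def test_constant_pad_outside_segment_is_inert(self):
        rec, events = self._trial_and_events()
        pad = np.tile(rec.acc[-1], (120, 1))
        padded = _recording(
            np.vstack([rec.acc, pad]), np.vstack([rec.gyr, np.tile(rec.gyr[-1], (120, 1))])
        )
        f1 = extract_wearable_features(rec, events).as_dict()
        f2 = extract_wearable_features(padded, events).as_dict()
        for key, v1 in f1.items():
            assert f2[key] == pytest.approx(v1, rel=1e-3, abs=1e-6), key

    def test_jerk_scale_monotonicity(self, quiet_signal_spec):
        """Doubling the latent jerk scale raises extracted peak ankle jerk."""
        from gaitcog.simulate import LatentProfile

        wins = 0
        spec = dataclasses.replace(quiet_signal_spec, noise_sd=0.25, trial_duration=6.0,
                                   n_repeats=1)
        for rep in range(20):
            base_profile = LatentProfile(
                participant_id="A", latent_motor_severity=0.0, latent_cognition=0.0,
                more_affected_side="left", stride_frequency=1.0,
                stride_length_true={"more": 1.2, "less": 1.2},
                jerk_scale_true=1.0, seed=1000 + rep,
            )
            high_profile = dataclasses.replace(base_profile, jerk_scale_true=2.0)
            def lank_fw_jerk(profile):
                trials = generate_imu_trials(profile, spec)
                rec = next(t for t in trials if t.placement == "LANK" and t.task == "FW")
                ank = next(t for t in trials if t.placement == "MANK" and t.task == "FW")
                events = detect_gait_cycles(ank)
                return extract_wearable_features(rec, events).max_jerk
            if lank_fw_jerk(high_profile) > lank_fw_jerk(base_profile):
                wins += 1
        assert wins >= 18


class TestSpatiotemporal:
    def test_noiseless_stride_speed_and_phases(self, profile, quiet_signal_spec):
        trial = generate_mocap_trial(profile, quiet_signal_spec, task="FW")
        st_params = extract_spatiotemporal(trial)
        assert st_params.stride_length_more == pytest.approx(1.2, abs=0.01)
        assert st_params.stride_length_less == pytest.approx(1.2, abs=0.01)
        assert st_params.walking_speed == pytest.approx(1.2, abs=0.01)
        total = (
            st_params.single_support_more
            + st_params.single_support_less
            + st_params.double_support
        )
        assert total == pytest.approx(100.0, abs=0.1)

    def test_coordination_matches_configured_offset(self, profile):
        spec = SignalSpec(noise_sd=0.0, marker_noise_sd=0.0,
                          coordination_offset=(8.0, 6.0))
        trial = generate_mocap_trial(profile, spec, task="FW")
        st_params = extract_spatiotemporal(trial)
        assert st_params.coord_ma_la == pytest.approx(8.0, abs=1.0)
        assert st_params.coord_la_ma == pytest.approx(6.0, abs=1.0)

    def test_too_few_contacts_rejected(self, profile, quiet_signal_spec):
        trial = generate_mocap_trial(profile, quiet_signal_spec, task="FW")
        broken = dataclasses.replace(
            trial, contacts={"more": trial.contacts["more"][:1], "less": trial.contacts["less"]}
        )
        with pytest.raises(ValueError):
            extract_spatiotemporal(broken)
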