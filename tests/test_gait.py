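"""Tests of filtering, truncation, step detection and gait parametrisation."""

import numpy as np
import pytest

from naturegait import (
    GeneratorConfig,
    MarkerTrajectory,
    StepEvent,
    TrueTrialParams,
    compute_gait_params,
    compute_velocity,
    detect_steps,
    lowpass_filter,
    qc_trial,
    summarize_trial,
    synthesize_trial_trajectory,
    truncate_trial,
)
from naturegait.datatypes import (
    QC_MISSING_MARKERS,
    QC_OVERLONG_STEP,
    QC_SAME_FOOT_REPEAT,
    QC_TOO_FEW_STEPS,
)
from naturegait.gait import find_stationary_periods


def make_trajectory(signal, fs=100.0):
    """All three markers carry the same 1D signal on every axis."""
    signal = np.asarray(signal, dtype=float)
    t = np.arange(signal.size) / fs
    pos = np.column_stack([signal, signal, signal])
    return MarkerTrajectory(
        time=t,
        positions={m: pos.copy()
                   for m in ("hip", "left_foot", "right_foot")},
        sampling_rate=fs,
    )


def sinusoid_gain(freq, fs=100.0, duration=30.0, cutoff=5.0, order=2):
    t = np.arange(0, duration, 1.0 / fs)
    traj = make_trajectory(np.sin(2 * np.pi * freq * t), fs)
    out = lowpass_filter(traj, cutoff=cutoff, order=order)
    y = out.positions["hip"][:, 1]
    mid = slice(len(t) // 3, 2 * len(t) // 3)
    # quadrature projection of the central third onto the probe frequency
    return 2.0 * np.abs(np.mean(y[mid] * np.exp(-2j * np.pi * freq * t[mid])))


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        traj = make_trajectory(np.full(500, 1.0))
        out = lowpass_filter(traj)
        assert np.allclose(out.positions["hip"], 1.0, atol=1e-12)

    @pytest.mark.parametrize("freq, expected", [
        (1.0, 1.0 / (1.0 + (1.0 / 5.0) ** 4)),    # 0.9984
        (20.0, 1.0 / (1.0 + (20.0 / 5.0) ** 4)),  # 0.0039
    ])
    def test_gain_matches_squared_butterworth_magnitude(self, freq,
                                                        expected):
        assert sinusoid_gain(freq) == pytest.approx(expected, rel=0.01)

    def test_zero_phase(self):
        """Cross-correlation between input and filtered 2 Hz sinusoid
        peaks at lag zero."""
        fs = 100.0
        t = np.arange(0, 20, 1.0 / fs)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass_filter(make_trajectory(x, fs)).positions["hip"][:, 1]
        mid = slice(200, 1800)
        lags = range(-10, 11)
        xc = [np.dot(x[mid], np.roll(y, lag)[mid]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_too_short_trajectory_reports_minimum(self):
        traj = make_trajectory(np.zeros(30))
        with pytest.raises(ValueError, match="minimum is 60"):
            lowpass_filter(traj)

    def test_preserves_length_and_timestamps(self):
        traj = make_trajectory(np.random.default_rng(0).normal(size=400))
        out = lowpass_filter(traj)
        assert out.n_samples == traj.n_samples
        assert np.array_equal(out.time, traj.time)


class TestTruncation:
    def _walk(self, span=12.0, v=1.25, fs=100.0):
        t = np.arange(0, span / v + 1.0 / fs, 1.0 / fs)
        y = v * t
        pos = np.column_stack([np.zeros_like(y), y, np.ones_like(y)])
        return MarkerTrajectory(
            time=t, positions={m: pos.copy() for m in
                               ("hip", "left_foot", "right_foot")},
            sampling_rate=fs)

    def test_retained_span_is_9_5_m(self):
        traj = self._walk()
        out = truncate_trial(traj)
        hip_y = out.positions["hip"][:, 1]
        spacing = 1.25 / 100.0
        assert hip_y[-1] - hip_y[0] == pytest.approx(9.5, abs=2 * spacing)

    def test_idempotent(self):
        once = truncate_trial(self._walk())
        twice = truncate_trial(once)
        assert twice.n_samples == once.n_samples
        assert np.array_equal(twice.positions["hip"],
                              once.positions["hip"])

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="does not exceed"):
            truncate_trial(self._walk(span=2.0))


class TestStepDetection:
    def test_roundtrip_positions(self, gen_config, reference_trial):
        traj = synthesize_trial_trajectory(reference_trial, gen_config,
                                           noise_sd=0.0)
        truncated = truncate_trial(lowpass_filter(traj))
        events = detect_steps(truncated)
        truth = traj.meta["truth"]["stances"]
        t0, t1 = truncated.time[0], truncated.time[-1]
        fully_inside = [s for s in truth
                        if s["landing_time"] >= t0
                        and s["lifting_time"] <= t1]
        truth_y = np.array([s["position_y"] for s in truth])
        # every fully visible stance is recovered at its position
        detected_y = np.array([e.position_y for e in events])
        for s in fully_inside:
            assert np.min(np.abs(detected_y - s["position_y"])) < 0.005
        # and nothing spurious appears
        for y in detected_y:
            assert np.min(np.abs(truth_y - y)) < 0.005

    def test_single_stationary_foot(self):
        fs = 100.0
        t = np.arange(0, 8, 1.0 / fs)
        y = 1.5 * t
        hip = np.column_stack([np.zeros_like(t), y, np.ones_like(t)])
        still = np.column_stack([np.zeros_like(t), np.full_like(t, 2.0),
                                 np.zeros_like(t)])
        traj = MarkerTrajectory(
            time=t,
            positions={"hip": hip, "left_foot": still.copy(),
                       "right_foot": hip.copy()},
            sampling_rate=fs)
        periods = find_stationary_periods(traj, "left_foot")
        assert len(periods) == 1
        assert periods[0].start_index <= 10
        assert periods[0].end_index >= traj.n_samples - 11

    def test_subthreshold_noise_cannot_change_step_count(
            self, gen_config, reference_trial):
        """Noise far below the 5 cm criterion changes neither the count
        nor the positions beyond 2 mm, in >= 99% of repetitions."""
        clean = synthesize_trial_trajectory(reference_trial, gen_config,
                                            noise_sd=0.0)
        base_events = detect_steps(truncate_trial(lowpass_filter(clean)))
        base_y = np.sort([e.position_y for e in base_events])
        stable = 0
        n_rep = 40
        for rep in range(n_rep):
            noisy = synthesize_trial_trajectory(
                reference_trial, gen_config,
                rng=np.random.default_rng(1000 + rep), noise_sd=0.002)
            events = detect_steps(truncate_trial(lowpass_filter(noisy)))
            ys = np.sort([e.position_y for e in events])
            if len(ys) == len(base_y) and np.max(np.abs(ys - base_y)) < 0.002:
                stable += 1
        assert stable >= int(np.ceil(0.99 * n_rep))

    def test_no_stationary_periods_yields_too_few_flag(self):
        fs = 100.0
        t = np.arange(0, 8, 1.0 / fs)
        y = 1.5 * t
        moving = np.column_stack([np.zeros_like(t), y, np.ones_like(t)])
        traj = MarkerTrajectory(
            time=t, positions={m: moving.copy() for m in
                               ("hip", "left_foot", "right_foot")},
            sampling_rate=fs)
        events = detect_steps(traj)
        assert events == []
        assert QC_TOO_FEW_STEPS in qc_trial(traj, events)


def constant_gait_events(n_per_foot=6, step=0.70, half_stride=0.56):
    """Alternating L/R events advancing by a constant step length."""
    events = []
    for i in range(2 * n_per_foot):
        foot = "left" if i % 2 == 0 else "right"
        t = i * half_stride
        events.append(StepEvent(
            foot=foot, position=np.array([0.0, i * step, 0.0]),
            landing_time=t, lifting_time=t + 0.7))
    return events


class TestGaitParams:
    def test_constant_gait(self):
        params = compute_gait_params(constant_gait_events())
        assert np.allclose(params.step_lengths, 0.70)
        assert np.allclose(params.stride_times, 1.12)
        assert params.step_lengths.std() == pytest.approx(0.0, abs=1e-12)
        assert not params.qc_flags

    def test_first_last_removed_per_foot(self):
        params = compute_gait_params(constant_gait_events(n_per_foot=6))
        # 6 events per foot -> 4 usable per foot -> 8 step lengths
        assert params.n_steps_used == 8
        assert len(params.stride_times) == 2 * 3

    def test_overlong_step_reported_and_flagged(self):
        events = constant_gait_events()
        for e in events[6:]:
            e.position[1] += 0.70  # one 1.40 m advance mid-walk
        params = compute_gait_params(events)
        assert QC_OVERLONG_STEP in params.qc_flags
        assert np.max(params.step_lengths) == pytest.approx(1.40)

    def test_too_few_events_flagged(self):
        params = compute_gait_params(constant_gait_events(n_per_foot=4))
        assert QC_TOO_FEW_STEPS in params.qc_flags


class TestVelocity:
    def test_arithmetic(self):
        fs = 100.0
        t = np.arange(0, 7.6 + 1 / fs, 1.0 / fs)
        y = 9.5 / 7.6 * t
        pos = np.column_stack([np.zeros_like(t), y, np.ones_like(t)])
        traj = MarkerTrajectory(
            time=t, positions={m: pos.copy() for m in
                               ("hip", "left_foot", "right_foot")},
            sampling_rate=fs)
        assert compute_velocity(traj) == pytest.approx(1.25, rel=1e-6)

    def test_stationary_hip_zero(self):
        traj = make_trajectory(np.zeros(200))
        assert compute_velocity(traj) == 0.0

    def test_roundtrip_with_noise(self, gen_config):
        params = TrueTrialParams("P01", "n000", 1, 1.10, 0.616, 1.12, 15)
        traj = synthesize_trial_trajectory(
            params, gen_config, rng=np.random.default_rng(77))
        summary = summarize_trial(traj)
        assert summary.mean_velocity == pytest.approx(1.10, abs=0.01)

    def test_velocity_consistency_with_step_parameters(self, gen_config,
                                                       reference_trial):
        summary = summarize_trial(synthesize_trial_trajectory(
            reference_trial, gen_config, noise_sd=0.0))
        implied = summary.mean_step_length / (summary.mean_stride_time / 2)
        assert implied == pytest.approx(summary.mean_velocity, rel=0.05)


class TestQc:
    def test_clean_trial_unflagged(self, gen_config, reference_trial):
        summary = summarize_trial(synthesize_trial_trajectory(
            reference_trial, gen_config, rng=np.random.default_rng(8)))
        assert summary.qc_flags == set()

    @pytest.mark.parametrize("fault, flag", [
        ("overlong_step", QC_OVERLONG_STEP),
        ("same_foot_repeat", QC_SAME_FOOT_REPEAT),
        ("missing_markers", QC_MISSING_MARKERS),
    ])
    def test_constructed_faults_detected(self, gen_config, reference_trial,
                                         fault, flag):
        traj = synthesize_trial_trajectory(
            reference_trial, gen_config,
            rng=np.random.default_rng(9), faults=[fault])
        summary = summarize_trial(traj)
        assert flag in summary.qc_flags

    def test_overlong_event_pair_flagged(self):
        events = constant_gait_events()
        for e in events[6:]:
            e.position[1] += 0.65  # a 1.35 m step
        traj = synthesize_trial_trajectory(
            TrueTrialParams("P", "i", 1, 1.25, 0.70, 1.12, 13),
            GeneratorConfig(seed=0), noise_sd=0.0)
        assert QC_OVERLONG_STEP in qc_trial(traj, events)


class TestRoundTripIdentity:
    def test_noise_free_recovery_below_one_percent(self, gen_config,
                                                   reference_trial):
        summary = summarize_trial(synthesize_trial_trajectory(
            reference_trial, gen_config, noise_sd=0.0))
        assert summary.mean_velocity == pytest.approx(1.25, rel=0.01)
        assert summary.mean_step_length == pytest.approx(0.70, rel=0.01)
        assert summary.mean_stride_time == pytest.approx(1.12, rel=0.01)
        assert summary.step_length_sd < 0.005
        assert summary.stride_time_sd < 0.010
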