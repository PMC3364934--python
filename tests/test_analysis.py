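import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycloclock.analysis import (ClassifierConfig, PeakList, SyntheticSpec,
                                 classify_dynamics, detect_peaks,
                                 estimate_period, phase_in_ld,
                                 split_amplitude_classes, stroboscopic_map,
                                 synthetic_trace)
from cycloclock.clock import LDSchedule
from cycloclock.core import ModelSpec, SimulationConfig, Trajectory, integrate


def make_traj(times, **series):
    return Trajectory(times=times, states=np.zeros((times.size, 0)),
                      state_names=(), observable_series=series, params_used=[])


class TestDetectPeaks:
    def test_sinusoid_24h(self):
        t = np.arange(0, 240, 0.1)
        peaks = detect_peaks(np.sin(2 * np.pi * t / 24), t, 0.05)
        assert len(peaks) == 10
        assert np.allclose(np.diff(peaks.peak_times), 24.0, atol=0.2)

    def test_constant_series_empty(self):
        t = np.arange(0, 100, 0.1)
        assert len(detect_peaks(np.ones_like(t), t, 0.05)) == 0

    def test_empty_series_raises(self):
        with pytest.raises(ValueError, match="empty"):
            detect_peaks(np.array([]), np.array([]))

    def test_two_scale_spike_train_keeps_large_only(self):
        t = np.arange(0, 240, 0.1)
        big_at = np.arange(10, 240, 24.0)
        small_at = np.arange(22, 240, 24.0)
        y = np.zeros_like(t)
        for c in big_at:
            y += 1.0 * np.exp(-0.5 * ((t - c) / 0.8) ** 2)
        for c in small_at:
            y += 0.01 * np.exp(-0.5 * ((t - c) / 0.8) ** 2)
        peaks = detect_peaks(y, t, min_prominence=0.05)
        assert len(peaks) == len(big_at)
        assert np.allclose(sorted(peaks.peak_times), big_at, atol=0.2)


class TestAmplitudeClasses:
    def test_bimodal_split(self):
        pk = PeakList(np.arange(4.0), np.array([1.0, 1.1, 0.01, 0.012]))
        cls = split_amplitude_classes(pk)
        assert cls.bimodal
        assert cls.separation == pytest.approx(95.45, rel=0.01)
        assert sorted(cls.labels) == ["large", "large", "minute", "minute"]

    def test_unimodal_all_large(self):
        pk = PeakList(np.arange(3.0), np.array([1.0, 1.05, 0.98]))
        cls = split_amplitude_classes(pk)
        assert not cls.bimodal
        assert all(cls.labels == "large")

    def test_single_peak_large(self):
        cls = split_amplitude_classes(PeakList(np.array([1.0]), np.array([1.0])))
        assert list(cls.labels) == ["large"]

    def test_no_peaks_raises(self):
        with pytest.raises(ValueError):
            split_amplitude_classes(PeakList(np.array([]), np.array([])))


class TestEstimatePeriod:
    def test_exact_trains(self):
        assert estimate_period(PeakList(np.array([0., 24, 48, 72]),
                                        np.ones(4))) == (24.0, 0.0)
        assert estimate_period(PeakList(np.array([0., 20, 40]),
                                        np.ones(3)))[0] == pytest.approx(20.0)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError, match="insufficient"):
            estimate_period(PeakList(np.array([0., 24]), np.ones(2)))

    def test_jittered_train_statistics(self):
        rng = np.random.default_rng(42)
        jitter = rng.uniform(-0.5, 0.5, size=50)
        times = 24.0 * np.arange(50) + jitter
        mean, cv = estimate_period(PeakList(times, np.ones(50)))
        # oracle: statistics of the generated intervals themselves
        iv = np.diff(times)
        assert mean == pytest.approx(np.mean(iv))
        assert cv == pytest.approx(np.std(iv) / np.mean(iv))
        assert abs(mean - 24.0) < 0.2
        assert cv < 0.02


class TestStroboscopicMap:
    @pytest.mark.parametrize("mult,expected", [(1, 1), (2, 2), (3, 3)])
    def test_locked_multiplicity(self, mult, expected):
        t = np.arange(0, 24 * mult * 40, 0.1)
        y = np.sin(2 * np.pi * t / (24.0 * mult))
        traj = make_traj(t, Cdk1=y, Cdk2=np.cos(2 * np.pi * t / (24.0 * mult)))
        res = stroboscopic_map(traj, 24.0, ("Cdk1", "Cdk2"), t_transient=0.0)
        assert res.distinct == expected

    def test_too_short_raises(self):
        t = np.arange(0, 48, 0.1)
        traj = make_traj(t, Cdk1=np.sin(t), Cdk2=np.cos(t))
        with pytest.raises(ValueError, match="too short"):
            stroboscopic_map(traj, 24.0, ("Cdk1", "Cdk2"))

    def test_chaotic_duffing_counts_grow(self):
        # literature-standard chaotic forced Duffing oscillator,
        # integrated with the same engine used for the models
        delta, gamma, omega = 0.3, 0.5, 1.2

        def rhs(t, y, p):
            return np.array([
                y[1],
                y[0] - y[0] ** 3 - delta * y[1] + gamma * np.cos(omega * t),
            ])

        model = ModelSpec(state_names=("x", "v"), rhs=rhs,
                          observables={"x": lambda t, s, p: s[:, 0],
                                       "v": lambda t, s, p: s[:, 1]})
        T = 2 * np.pi / omega
        cfg = SimulationConfig(t_end=300 * T, dt_out=T / 50, rel_tol=1e-9,
                               abs_tol=1e-11, method="DOP853")
        traj = integrate(model, [0.1, 0.0], cfg)
        mask = traj.times <= 150 * T
        truncated = Trajectory(
            times=traj.times[mask], states=traj.states[mask],
            state_names=traj.state_names,
            observable_series={k: v[mask]
                               for k, v in traj.observable_series.items()},
            params_used=[])
        short = stroboscopic_map(truncated, T, ("x", "v"),
                                 t_transient=50 * T, min_cycles=5)
        full = stroboscopic_map(traj, T, ("x", "v"), t_transient=50 * T,
                                min_cycles=5)
        assert full.distinct > short.distinct
        assert full.distinct > 100  # no saturation at a small point count


class TestClassifier:
    CFG = ClassifierConfig(t_transient=260.0)

    @pytest.mark.parametrize("period", [12.0, 24.0, 36.0, 48.0])
    @pytest.mark.parametrize("ratio", [1.0, 10.0, 100.0])
    @pytest.mark.parametrize("jitter", [0.0, 0.01])
    def test_fixture_grid_full_accuracy(self, period, ratio, jitter):
        spec = SyntheticSpec(period=period, amplitude_ratio=ratio,
                             jitter=jitter, seed=7)
        fx = synthetic_trace(spec)
        got = classify_dynamics(fx.trajectory, self.CFG)
        assert got.label == fx.truth_label

    def test_endoreplication_fixture(self):
        fx = synthetic_trace(SyntheticSpec(period=24.0, cdk1_scale=0.001))
        assert fx.truth_label == "endoreplication"
        assert classify_dynamics(fx.trajectory, self.CFG).label == "endoreplication"

    def test_tetraploid_fixture(self):
        fx = synthetic_trace(SyntheticSpec(period=24.0, cdk2_per_cdk1=2))
        assert fx.truth_label == "tetraploid_pattern"
        assert classify_dynamics(fx.trajectory, self.CFG).label == "tetraploid_pattern"

    def test_constant_trace_quiescent(self):
        t = np.arange(0, 1200, 0.1)
        traj = make_traj(t, Cdk1=np.full_like(t, 0.2), Cdk2=np.full_like(t, 0.3))
        assert classify_dynamics(traj, self.CFG).label == "quiescent"

    def test_tiny_ripple_on_plateau_quiescent(self):
        t = np.arange(0, 1200, 0.1)
        ripple = 0.005 * np.sin(2 * np.pi * t / 24)
        traj = make_traj(t, Cdk1=0.2 + ripple, Cdk2=0.3 + ripple)
        assert classify_dynamics(traj, self.CFG).label == "quiescent"

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           shift_cycles=st.integers(min_value=0, max_value=5))
    @settings(max_examples=10, deadline=None)
    def test_invariance_scaling_and_shift(self, scale, shift_cycles):
        fx = synthetic_trace(SyntheticSpec(period=24.0, seed=3))
        traj = fx.trajectory
        shifted = Trajectory(
            times=traj.times + 24.0 * shift_cycles,
            states=traj.states,
            state_names=traj.state_names,
            observable_series={k: scale * v
                               for k, v in traj.observable_series.items()},
            params_used=[],
        )
        cfg = ClassifierConfig(t_transient=260.0 + 24.0 * shift_cycles)
        assert classify_dynamics(shifted, cfg).label == fx.truth_label

    @pytest.mark.parametrize("period,jitter", [(12.0, 0.01), (24.0, 0.01),
                                               (36.0, 0.0), (48.0, 0.01)])
    def test_period_recovery_within_1pct(self, period, jitter):
        fx = synthetic_trace(SyntheticSpec(period=period, jitter=jitter, seed=5))
        sub = fx.trajectory.after(260.0)
        pk = detect_peaks(sub.series("Cdk1"), sub.times, 0.05)
        mean, _ = estimate_period(pk)
        assert abs(mean - period) / period < 0.01


class TestPhaseInLD:
    def test_peak_phase_examples(self, ld_schedule):
        pk = PeakList(np.array([158.0]), np.array([1.0]))
        res = phase_in_ld(pk, ld_schedule)
        assert res.phases[0] == pytest.approx(14.0)
        assert res.all_in_late_L

        pk = PeakList(np.array([20.0]), np.array([1.0]))
        res = phase_in_ld(pk, ld_schedule)
        assert res.phases[0] == pytest.approx(20.0)
        assert not res.all_in_late_L

    def test_empty_raises(self, ld_schedule):
        with pytest.raises(ValueError, match="empty"):
            phase_in_ld(PeakList(np.array([]), np.array([])), ld_schedule)

    def test_circular_mean_wraps(self, ld_schedule):
        pk = PeakList(np.array([23.5, 24.5]), np.ones(2))
        res = phase_in_ld(pk, ld_schedule)
        assert res.circular_mean == pytest.approx(0.0, abs=0.01) or \
            res.circular_mean == pytest.approx(24.0, abs=0.01)
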