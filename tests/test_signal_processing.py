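import numpy as np
import pytest

from conftest import make_noise_stack
from metapanel.signal_processing import (
    ChannelMap,
    RateConfig,
    channel_trace,
    default_channel_map,
    detect_bad_sensors,
    extract_rate,
    fit_double_exp,
    lowpass,
    temporal_bin,
)
from metapanel.models import initial_slope
from metapanel.synthetic_data import (
    FrameStack,
    SensorModel,
    control_kinetics,
    linear_kinetics,
    simulate_frame_stack,
)


class TestChannelMap:
    def test_default_geometry(self, cmap):
        assert cmap.channels == [1, 2, 3, 4]
        for ch in cmap.channels:
            assert len(cmap.sensors(ch)) == 48

    def test_empty_channel_rejected(self):
        grid = np.zeros((4, 4), dtype=int)
        grid[0, 0] = 1
        with pytest.raises(ValueError):
            ChannelMap(channel_grid=grid, excluded=frozenset({(0, 0)}))


class TestLowpass:
    def test_constant_trace_unchanged(self):
        x = np.full(500, 1.73)
        assert np.allclose(lowpass(x), x, atol=1e-12)

    def test_stopband_attenuation(self):
        t = np.arange(2000)
        x = np.sin(np.pi * 0.4 * t)  # 0.4 × Nyquist
        y = lowpass(x)[200:-200]
        atten = 20 * np.log10(np.max(np.abs(y)) / 1.0)
        assert atten < -40.0

    def test_passband_preserved(self):
        t = np.arange(4000)
        x = np.sin(np.pi * 0.01 * t)
        y = lowpass(x)[500:-500]
        assert np.max(np.abs(y)) == pytest.approx(1.0, rel=0.01)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.ones(20))


class TestDetectBadSensors:
    def test_healthy_identical_sensors_pass(self, cmap):
        stack = make_noise_stack(seed=1)
        assert detect_bad_sensors(stack, cmap) == set()

    def test_single_frozen_sensor_detected(self, cmap):
        stack = make_noise_stack(seed=2)
        stack.frames[:, 3, 1] = 1.73  # frozen at constant value
        assert detect_bad_sensors(stack, cmap) == {(3, 1)}

    def test_railed_sensor_detected(self, cmap):
        stack = make_noise_stack(seed=3)
        stack.frames[:, 5, 5] = 0.0
        assert detect_bad_sensors(stack, cmap) == {(5, 5)}

    def test_slope_outlier_detected(self, cmap):
        stack = make_noise_stack(seed=4, n_frames=800)
        stack.frames[:, 8, 9] += np.linspace(0, 0.2, 800)  # strong artifact
        assert (8, 9) in detect_bad_sensors(stack, cmap)

    def test_dead_fraction_monte_carlo(self, cmap):
        kin = linear_kinetics("glutamate")
        kins = {1: control_kinetics(), 2: kin, 3: kin, 4: kin}
        fracs = []
        for seed in range(100):
            stack = simulate_frame_stack(
                {1: 0, 2: 50, 3: 150, 4: 250}, cmap, kins,
                SensorModel(dead_fraction=0.02), seed=seed, duration=8.0,
            )
            fracs.append(len(detect_bad_sensors(stack, cmap)) / 192)
        se = np.sqrt(0.02 * 0.98 / (192 * 100))
        assert abs(np.mean(fracs) - 0.02) < 3 * se

    def test_fully_dead_channel_raises(self, cmap):
        stack = make_noise_stack(seed=5)
        for r, c in cmap.sensors(2):
            stack.frames[:, r, c] = 0.0
        with pytest.raises(ValueError, match="zero live sensors"):
            detect_bad_sensors(stack, cmap)


class TestChannelTrace:
    def test_identical_sensors_average_to_one(self, cmap):
        stack = make_noise_stack(seed=6, sd=0.0)
        traces = channel_trace(stack, cmap)
        r, c = cmap.sensors(1)[0]
        assert np.allclose(traces[1], stack.frames[:, r, c])

    def test_noise_reduction_by_spatial_averaging(self, cmap):
        sds = []
        for seed in range(30):
            stack = make_noise_stack(seed=seed, n_frames=200, sd=1e-3)
            traces = channel_trace(stack, cmap)
            sds.append(np.std(traces[1]))
        assert np.mean(sds) == pytest.approx(1e-3 / np.sqrt(48), rel=0.10)

    def test_excluded_outlier_does_not_perturb_mean(self, cmap):
        stack = make_noise_stack(seed=7, sd=0.0)
        clean = channel_trace(stack, cmap)[1]
        victim = cmap.sensors(1)[10]
        stack.frames[:, victim[0], victim[1]] = 3.0
        with_exclusion = channel_trace(stack, cmap, exclusions={victim})[1]
        assert np.allclose(with_exclusion, clean)

    def test_empty_channel_rejected(self, cmap):
        stack = make_noise_stack(seed=8)
        with pytest.raises(ValueError):
            channel_trace(stack, cmap, exclusions=set(cmap.sensors(1)))


class TestTemporalBin:
    def test_300s_gives_300_points(self):
        t = np.arange(10950) / 36.5
        bt, bv = temporal_bin(t, np.ones_like(t))
        assert len(bt) == 300

    def test_constant_preserved(self):
        t = np.arange(400) / 36.5
        bt, bv = temporal_bin(t, np.full_like(t, 2.5))
        assert np.allclose(bv, 2.5)

    def test_linear_ramp_slope_preserved(self):
        t = np.arange(2000) / 36.5
        m = 0.01
        bt, bv = temporal_bin(t, m * t)
        slope = np.polyfit(bt, bv, 1)[0]
        assert slope == pytest.approx(m, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            temporal_bin(np.arange(10) / 36.5, np.ones(10))


class TestFitDoubleExp:
    def test_exact_single_exponential_recovery(self):
        t = np.arange(300) + 0.5
        y = 1730.0 - 40.0 * (1 - np.exp(-0.02 * t))
        fit, rmse = fit_double_exp(t, y)
        assert rmse < 1e-6
        assert abs(initial_slope(fit)) == pytest.approx(0.8, rel=1e-4)

    def test_flat_trace_zero_slope(self):
        t = np.arange(100) + 0.5
        fit, rmse = fit_double_exp(t, np.full(100, 486.0))
        assert abs(initial_slope(fit)) < 1e-9


class TestExtractRate:
    def test_noiseless_single_exponential_rate(self, cmap, quiet_sensor):
        kin = linear_kinetics("glutamate")
        kins = {1: control_kinetics(), 2: kin, 3: control_kinetics(), 4: control_kinetics()}
        stack = simulate_frame_stack(
            {1: 0, 2: 160.0, 3: 0, 4: 0}, cmap, kins, quiet_sensor, seed=0, duration=300.0
        )
        truth = stack.metadata["channel_truth_mV_s"][2]
        res = extract_rate(stack, cmap)
        assert res[2].rate == pytest.approx(truth, rel=0.01)
        assert res[2].n_sensors_used == 48

    def test_drift_only_stack_reports_drift(self, cmap):
        kin = linear_kinetics("glutamate")
        stack = simulate_frame_stack(
            {i: 0.0 for i in range(1, 5)}, cmap, {i: kin for i in range(1, 5)},
            SensorModel(dead_fraction=0.0), seed=11, duration=300.0,
        )
        res = extract_rate(stack, cmap)
        # configured illuminated drift is 0.9 µV/s
        assert res[1].rate * 1e3 == pytest.approx(0.9, abs=0.4)

    def test_dark_flat_stack_rate_zero(self, cmap):
        sm = SensorModel(noise_sd=0.0, dead_fraction=0.0, drift_dark=0.0)
        stack = simulate_frame_stack(
            {i: 0.0 for i in range(1, 5)}, cmap,
            {i: control_kinetics() for i in range(1, 5)},
            sm, seed=0, duration=60.0, illuminated=False,
        )
        stack.frames[:] = 0.486  # exactly static acquisition
        res = extract_rate(stack, cmap)
        assert all(r.rate < 1e-9 for r in res.values())

    def test_offset_equivariance(self, cmap, glutamate_run):
        base = extract_rate(glutamate_run, cmap)
        shifted = FrameStack(
            times=glutamate_run.times,
            frames=glutamate_run.frames + 0.25,
            metadata=dict(glutamate_run.metadata),
        )
        res = extract_rate(shifted, cmap)
        for ch in base:
            assert res[ch].rate == pytest.approx(base[ch].rate, rel=1e-6)

    def test_amplitude_scaling_scales_rate(self, cmap, quiet_sensor):
        kin = linear_kinetics("glutamate")
        kins = {1: control_kinetics(), 2: kin, 3: control_kinetics(), 4: control_kinetics()}
        stack = simulate_frame_stack(
            {1: 0, 2: 100.0, 3: 0, 4: 0}, cmap, kins, quiet_sensor, seed=1, duration=300.0
        )
        lam = 2.0
        baseline = 1.730
        scaled = FrameStack(
            times=stack.times,
            frames=baseline + lam * (stack.frames - baseline),
            metadata=dict(stack.metadata),
        )
        r0 = extract_rate(stack, cmap)[2].rate
        r1 = extract_rate(scaled, cmap)[2].rate
        assert r1 == pytest.approx(lam * r0, rel=0.01)

    def test_end_to_end_linearity_oracle(self, cmap, quiet_sensor):
        # 30 seeded noiseless runs across the linear range: extracted vs
        # configured rate has slope 1 +- 0.05 and R² > 0.99
        kin = linear_kinetics("glutamate")
        kins = {1: control_kinetics(), 2: kin, 3: control_kinetics(), 4: control_kinetics()}
        truths, rates = [], []
        for i, conc in enumerate(np.linspace(20.0, 320.0, 30)):
            stack = simulate_frame_stack(
                {1: 0, 2: conc, 3: 0, 4: 0}, cmap, kins, quiet_sensor,
                seed=i, duration=300.0,
            )
            truths.append(stack.metadata["channel_truth_mV_s"][2])
            rates.append(extract_rate(stack, cmap)[2].rate)
        truths, rates = np.asarray(truths), np.asarray(rates)
        assert np.max(np.abs(rates - truths) / truths) < 0.01
        slope, intercept = np.polyfit(truths, rates, 1)
        pred = slope * truths + intercept
        r2 = 1 - np.sum((rates - pred) ** 2) / np.sum((rates - rates.mean()) ** 2)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 > 0.99

    def test_anomalous_channel_flagged(self, cmap):
        stack = make_noise_stack(seed=12, n_frames=800, sd=1e-4)
        rng = np.random.default_rng(0)
        for r, c in cmap.sensors(3):  # wreck one channel with a huge artifact
            stack.frames[:, r, c] += 0.3 * np.sin(2 * np.pi * 0.05 * np.arange(800) / 36.5)
        res = extract_rate(stack, cmap, RateConfig(detect_bad=False))
        assert "anomalous" in res[3].flags
        assert not res[1].flags
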