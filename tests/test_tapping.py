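"""Tests for tap detection, cycle timing, speed binning and derived indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiscope.model import ModelParams, ProtocolSpec, simulate_trial
from fatiscope.tapping import (
    BinnedSeries,
    TapStream,
    bin_speed,
    cycle_times,
    detect_taps,
    fit_slope,
    normalise_to_control,
    pacing_compliance,
    pearson_r,
    recovery_index,
    sliding_rate,
    slowing_pct,
)


def make_stream(times, effectors=None, cycle=("tap",)):
    times = np.asarray(times, dtype=float)
    if effectors is None:
        effectors = ["tap"] * len(times)
    return TapStream(times, np.asarray(effectors, dtype=object), cycle)


def alternating_stream(rate_hz=2.0, duration=30.0):
    """Two-effector alternation at a constant cycle rate."""
    cycle_T = 1.0 / rate_hz
    starts = np.arange(0.0, duration, cycle_T)
    times, effs = [], []
    for s in starts:
        times += [s, s + cycle_T / 2]
        effs += ["L", "R"]
    times.append(starts[-1] + cycle_T)  # closing anchor completes last cycle
    effs.append("L")
    return make_stream(times, effs, ("L", "R"))


class TestDetectTaps:
    def test_noiseless_pulse_train_recovered_exactly(self):
        fs = 1000.0
        trace = np.zeros(int(fs))
        onsets = np.arange(0, 1000, 250)  # 4 Hz
        for i in onsets:
            trace[i : i + 20] = 1.0
        stream = detect_taps(trace, fs)
        assert len(stream) == 4
        assert np.allclose(stream.times, onsets / fs)

    def test_refractory_merges_close_crossings(self):
        fs = 1000.0
        trace = np.zeros(200)
        trace[50:52] = 1.0
        trace[60:62] = 1.0  # 10 ms later
        stream = detect_taps(trace, fs, threshold=0.5, refractory_ms=50)
        assert len(stream) == 1

    def test_flat_trace_yields_empty_stream(self):
        stream = detect_taps(np.zeros(1000), 1000.0)
        assert len(stream) == 0

    def test_recovers_planted_taps_from_synthetic_force(self, rng):
        from fatiscope.cohort import generate_taps, render_force

        traj = simulate_trial(ModelParams(), ProtocolSpec.tap_then_rest(30.0, 5.0))
        stream = generate_taps(traj, jitter_cv=0.05, rng=rng)
        force = render_force(stream, fs=1000.0, duration=36.0, noise_sd=0.05, rng=rng)
        detected = detect_taps(force, fs=1000.0, refractory_ms=60)
        # every planted tap matched within 10 ms (threshold crossing lags the
        # pulse onset by a constant few ms), no spurious detections
        matched = sum(np.min(np.abs(detected.times - t)) < 10e-3 for t in stream.times)
        assert matched >= 0.99 * len(stream)
        assert len(detected) <= len(stream)


class TestCycleTimes:
    def test_alternating_taps(self):
        ct = cycle_times(alternating_stream(rate_hz=2.0, duration=3.0))
        assert np.allclose(ct, 0.5)

    def test_four_element_sequence(self):
        # sequence 4-1-3-2 repeated at 0.1 s per tap -> 0.4 s cycles
        seq = ["4", "1", "3", "2"]
        times = np.arange(0, 1.3, 0.1)
        effs = (seq * 4)[: len(times)]
        ct = cycle_times(make_stream(times, effs, tuple(seq)))
        assert np.allclose(ct, 0.4)

    def test_single_tap_gives_empty(self):
        assert len(cycle_times(make_stream([0.1]))) == 0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            cycle_times(make_stream([]))


class TestBinSpeed:
    def test_constant_rate(self):
        series = bin_speed(alternating_stream(2.0, 30.0), 10.0, duration=30.0, t0=0.0)
        assert np.allclose(series.values, 20.0)
        assert series.unit == "cycles per 10 s"

    def test_empty_stream_zero_bins(self):
        series = bin_speed(make_stream([]), 10.0, duration=30.0)
        assert np.allclose(series.values, 0.0)

    def test_cycle_conservation(self):
        stream = alternating_stream(3.3, 30.0)
        series = bin_speed(stream, 10.0, duration=30.0, t0=0.0)
        assert series.values.sum() == len(cycle_times(stream))

    def test_pairwise_aggregation_matches_double_width(self):
        stream = alternating_stream(2.7, 40.0)
        fine = bin_speed(stream, 5.0, duration=40.0, t0=0.0)
        coarse = bin_speed(stream, 10.0, duration=40.0, t0=0.0)
        paired = fine.values.reshape(-1, 2).sum(axis=1) / 2.0
        assert np.allclose(paired, coarse.values)

    def test_simulated_slowing_ratio(self, rng):
        from fatiscope.cohort import generate_taps

        traj = simulate_trial(ModelParams(), ProtocolSpec.tap_then_rest(30.0, 5.0))
        stream = generate_taps(traj, jitter_cv=0.0, rng=rng)
        series = bin_speed(stream, 10.0, duration=30.0, t0=0.0)
        assert series.values[2] / series.values[0] == pytest.approx(0.8, abs=0.05)

    def test_slowing_grows_then_plateaus_with_duration(self, rng):
        """1 s rate-based bins: more slowing for 30 s than 10 s, plateau by 50 s."""
        from fatiscope.cohort import generate_taps

        slows = {}
        for dur in (10.0, 30.0, 50.0):
            traj = simulate_trial(ModelParams(), ProtocolSpec.tap_then_rest(dur, 5.0))
            stream = generate_taps(traj, jitter_cv=0.0, rng=rng)
            series = bin_speed(stream, 1.0, duration=dur, t0=0.0, method="rate")
            slows[dur] = slowing_pct(series)
        assert 0 < slows[10.0] < slows[30.0]
        assert abs(slows[50.0] - slows[30.0]) < 3.0


class TestNormalisation:
    def make(self, values):
        edges = np.column_stack([np.arange(len(values)) * 10.0,
                                 (np.arange(len(values)) + 1) * 10.0])
        return BinnedSeries(edges, values, unit="cycles per 10 s")

    def test_identity(self):
        s = self.make([40.0, 36.0, 32.0])
        out = normalise_to_control(s, s)
        assert np.allclose(out.values, np.array([40, 36, 32]) / 36.0)

    def test_scalar_denominator(self):
        out = normalise_to_control(self.make([40.0, 36.0, 32.0]), self.make([40.0]))
        assert np.allclose(out.values, [1.0, 0.9, 0.8])

    def test_scale_invariance(self):
        a, b = self.make([40.0, 30.0, 20.0]), self.make([41.0, 39.0])
        base = normalise_to_control(a, b).values
        scaled = normalise_to_control(self.make([80.0, 60.0, 40.0]),
                                      self.make([82.0, 78.0])).values
        assert np.allclose(base, scaled)

    def test_zero_control_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalise_to_control(self.make([1.0]), self.make([0.0]))

    def test_unit_mismatch_rejected(self):
        other = self.make([1.0])
        other.unit = "mV"
        with pytest.raises(ValueError):
            normalise_to_control(self.make([1.0]), other)


class TestRecoveryIndexAndSlopes:
    def make(self, values):
        edges = np.column_stack([np.arange(len(values)) * 10.0,
                                 (np.arange(len(values)) + 1) * 10.0])
        return BinnedSeries(edges, values, unit="cycles per 10 s")

    def test_no_change_gives_zero(self):
        assert recovery_index(self.make([32.0]), self.make([32.0])) == 0.0

    def test_recovery_positive(self):
        assert recovery_index(self.make([38.0, 32.0]), self.make([38.0])) == 6.0

    def test_fit_slope_linear(self):
        assert fit_slope([40.0, 36.0, 32.0]) == pytest.approx(-4.0)
        assert fit_slope([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_fit_slope_matches_polyfit_oracle(self, rng):
        for _ in range(20):
            y = rng.normal(size=rng.integers(3, 12))
            x = np.arange(1, len(y) + 1, dtype=float)
            expected = np.polyfit(x, y, 1)[0]
            assert fit_slope(y) == pytest.approx(expected, abs=1e-10)

    def test_fit_slope_needs_two_points(self):
        with pytest.raises(ValueError):
            fit_slope([1.0])

    def test_pearson_r_exact_cases(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_r_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPacing:
    def test_compliance_extremes(self):
        assert pacing_compliance(np.full(50, 3.0), target=3.0) == 1.0
        assert pacing_compliance(np.full(50, 3.4), target=3.0, tol=0.2) == 0.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            pacing_compliance(np.array([]), 3.0)

    def test_simulated_paced_trial_high_compliance(self, rng):
        from fatiscope.cohort import generate_taps

        params = ModelParams()
        # a clearly sustainable pace (below the fatigued-speed floor)
        pace = 0.6 * params.v0
        traj = simulate_trial(params, ProtocolSpec.tap_then_rest(30.0, 5.0, pacing=pace))
        stream = generate_taps(traj, jitter_cv=0.02, rng=rng)
        rates = sliding_rate(stream, window=1.0)
        assert pacing_compliance(rates, target=pace, tol=0.2) > 0.9


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(0.05, 0.6), min_size=3, max_size=60))
def test_bin_conservation_property(intervals):
    """Total binned cycle count equals the number of completed cycles."""
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    stream = make_stream(times)
    series = bin_speed(stream, 1.0, duration=float(times[-1]) + 1e-6, t0=0.0)
    assert series.values.sum() * (1.0 / 10.0) == pytest.approx(len(times) - 1)
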