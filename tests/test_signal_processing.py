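"""Trace statistics against closed forms and Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valveverify.signal_processing import (dp_mean, ejection_window, inter_cycle_stats,
                                           periodic_extend, pressure_difference, q_mean,
                                           segment_cycles, stroke_volume, summarize,
                                           uncertainty_bounds)
from valveverify.synthetic_mockloop import (MockLoopSpec, add_pump_return, generate_flow_trace,
                                            generate_pressure_traces, scale_flow_to_co)
from valveverify.traces import TimeTrace, uniform_grid


def _periodic(n_cycles, T=0.8, dt=1e-3):
    t = uniform_grid(n_cycles * T, dt)
    return TimeTrace(t, np.sin(2 * np.pi * t / T) + 0.3 * np.cos(4 * np.pi * t / T))


class TestSegmentCycles:
    def test_exact_cycles_identical_members(self):
        ens = segment_cycles(_periodic(6), 0.8)
        assert ens.n_cycles == 6
        for c in ens.cycles[1:]:
            np.testing.assert_allclose(c.value, ens.cycles[0].value, atol=1e-12)

    def test_partial_cycle_dropped(self):
        t = uniform_grid(6.5 * 0.8, 1e-3)
        trace = TimeTrace(t, np.sin(2 * np.pi * t / 0.8))
        assert segment_cycles(trace, 0.8).n_cycles == 6

    def test_too_short_rejected(self):
        t = uniform_grid(0.9, 1e-3)
        with pytest.raises(ValueError):
            segment_cycles(TimeTrace(t, np.zeros(len(t))), 0.8)

    def test_noise_averaging_scales_as_sqrt_n(self):
        # sd of the cycle mean ~ sigma/sqrt(N) within 20% at N=50
        rng = np.random.default_rng(42)
        N, n, sigma = 50, 800, 0.5
        t = uniform_grid(N * 0.8, 1e-3)
        trace = TimeTrace(t, np.tile(np.sin(2 * np.pi * np.arange(n) / n), N)
                          + rng.normal(0, sigma, len(t)))
        ens = segment_cycles(trace, 0.8)
        assert np.mean(ens.sd_trace.value) == pytest.approx(sigma, rel=0.2)
        sd_of_mean = np.std(ens.mean_trace.value - np.sin(2 * np.pi * np.arange(n) / n))
        assert sd_of_mean == pytest.approx(sigma / np.sqrt(N), rel=0.2)


class TestPressureDifference:
    def test_identity_and_offset(self):
        t = uniform_grid(0.8, 1e-3)
        p = TimeTrace(t, 80 + 10 * np.sin(2 * np.pi * t / 0.8))
        assert np.all(pressure_difference(p, p).value == 0.0)
        shifted = TimeTrace(t, p.value + 40.0)
        np.testing.assert_allclose(pressure_difference(shifted, p).value, 40.0)

    def test_antisymmetry(self):
        t = uniform_grid(0.8, 1e-3)
        a = TimeTrace(t, np.sin(t)); b = TimeTrace(t, np.cos(t))
        np.testing.assert_allclose(pressure_difference(a, b).value,
                                   -pressure_difference(b, a).value)

    def test_mismatched_grids_rejected(self):
        a = TimeTrace(uniform_grid(0.8, 1e-3), np.zeros(800))
        b = TimeTrace(uniform_grid(0.8, 2e-3), np.zeros(400))
        with pytest.raises(ValueError):
            pressure_difference(a, b)


class TestPeriodicExtend:
    def test_identity_at_one(self):
        one = _periodic(1)
        np.testing.assert_array_equal(periodic_extend(one, 1).value, one.value)

    def test_six_repeats_equal_cycle_integrals(self):
        ext = periodic_extend(_periodic(1), 6)
        ens = segment_cycles(ext, 0.8)
        integrals = [np.trapezoid(c.value, c.t) for c in ens.cycles]
        np.testing.assert_allclose(integrals, integrals[0], atol=1e-12)

    def test_fourier_fundamental_is_cycle_rate(self):
        ext = periodic_extend(_periodic(1), 6)
        spec = np.abs(np.fft.rfft(ext.value - ext.value.mean()))
        freqs = np.fft.rfftfreq(len(ext), ext.dt)
        assert freqs[np.argmax(spec)] == pytest.approx(1.0 / 0.8, rel=1e-6)


class TestEjectionWindow:
    def _traces(self, shift=0.0):
        t = uniform_grid(0.8, 1e-3)
        dp = np.where((t >= 0.1 + shift) & (t <= 0.4 + shift), 30.0, -10.0)
        q = np.where(t < 0.42 + shift, 100.0, -5.0)
        z = np.zeros(len(t))
        return (TimeTrace(t, q), TimeTrace(t, 80 + dp), TimeTrace(t, 80 + z))

    def test_constructed_window(self):
        q, plv, pao = self._traces()
        t0, t1 = ejection_window(q, plv, pao)
        assert t0 == pytest.approx(0.1, abs=2e-3)
        assert t1 == pytest.approx(0.42, abs=2e-3)

    def test_fallback_to_dp_zero_crossing_when_flow_stays_positive(self):
        t = uniform_grid(0.8, 1e-3)
        dp = np.where((t >= 0.1) & (t <= 0.4), 30.0, -10.0)
        q = TimeTrace(t, np.full(len(t), 50.0))
        t0, t1 = ejection_window(q, TimeTrace(t, 80 + dp), TimeTrace(t, np.full(len(t), 80.0)))
        assert t1 == pytest.approx(0.4, abs=2e-3)

    def test_translation_equivariance(self):
        w0 = ejection_window(*self._traces(0.0))
        w1 = ejection_window(*self._traces(0.15))
        assert w1[0] - w0[0] == pytest.approx(0.15, abs=2e-3)
        assert w1[1] - w0[1] == pytest.approx(0.15, abs=2e-3)

    def test_no_crossing_raises(self):
        t = uniform_grid(0.8, 1e-3)
        flat = TimeTrace(t, np.zeros(len(t)))
        with pytest.raises(ValueError):
            ejection_window(flat, TimeTrace(t, np.full(len(t), 70.0)),
                            TimeTrace(t, np.full(len(t), 80.0)))


class TestFlowStatistics:
    def test_rectangular_pulse_q_mean(self):
        t = uniform_grid(0.8, 1e-3)
        q = TimeTrace(t, np.where((t >= 0.1) & (t <= 0.35), 200.0, 0.0))
        assert q_mean(q, (0.1, 0.35)) == pytest.approx(200.0, rel=0.01)

    def test_half_sine_q_mean_closed_form(self):
        t = uniform_grid(0.3, 1e-4)
        q = TimeTrace(t, 300.0 * np.sin(np.pi * t / 0.3))
        assert q_mean(q, (0.0, 0.3)) == pytest.approx(2 / np.pi * 300.0, rel=1e-3)

    def test_table_round_trip_143(self):
        # a rectangular trace constructed to have Qmean = 143 reproduces it
        t = uniform_grid(0.8, 1e-3)
        q = TimeTrace(t, np.where(t <= 0.3, 143.0, 0.0))
        assert q_mean(q, (0.0, 0.3)) == pytest.approx(143.0, abs=0.5)

    def test_stroke_volume_identities(self):
        t = uniform_grid(0.8, 1e-3)
        q = TimeTrace(t, np.where((t >= 0.1) & (t <= 0.35), 200.0, 0.0))
        w = (0.1, 0.35)
        assert stroke_volume(q, w) == pytest.approx(q_mean(q, w) * 0.25, rel=1e-9)

    def test_synthetic_d0_stroke_volume(self):
        spec = MockLoopSpec()  # d0: 3.2 L/min at 75 bpm
        plv, pao = generate_pressure_traces(spec)
        dp1 = segment_cycles(pressure_difference(plv, pao), spec.cycle_time).cycles[0]
        q1 = add_pump_return(scale_flow_to_co(generate_flow_trace(dp1, 1.0), 3.2, 75.0))
        q = TimeTrace(plv.t, np.tile(q1.value, spec.n_cycles))
        s = summarize(q, plv, pao, spec.cycle_time)
        assert s.stroke_volume == pytest.approx(42.7, abs=0.2)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_flow(self, scale):
        t = uniform_grid(0.5, 1e-3)
        q = TimeTrace(t, np.sin(np.pi * t / 0.5) * 100.0)
        q2 = TimeTrace(t, scale * q.value)
        w = (0.05, 0.4)
        assert q_mean(q2, w) == pytest.approx(scale * q_mean(q, w), rel=1e-9)
        assert stroke_volume(q2, w) == pytest.approx(scale * stroke_volume(q, w), rel=1e-9)


class TestDpMean:
    def test_constant_44(self):
        t = uniform_grid(0.8, 1e-3)
        dp = TimeTrace(t, np.where(t < 0.3, 44.0, -10.0))
        assert dp_mean(dp) == pytest.approx(44.0, rel=5e-3)

    def test_half_sine_closed_form(self):
        t = uniform_grid(0.8, 1e-4)
        v = np.where(t < 0.3, 69.0 * np.sin(np.pi * np.minimum(t, 0.3) / 0.3), -10.0)
        assert dp_mean(TimeTrace(t, v)) == pytest.approx(2 / np.pi * 69.0, rel=5e-3)

    def test_diastolic_plateau_does_not_affect_result(self):
        # the plateau level only moves the interpolated crossing inside one
        # sample, so agreement holds to sub-sample accuracy
        t = uniform_grid(0.8, 1e-3)
        a = dp_mean(TimeTrace(t, np.where(t < 0.3, 50.0, -5.0)))
        b = dp_mean(TimeTrace(t, np.where(t < 0.3, 50.0, -40.0)))
        assert a == pytest.approx(b, rel=2e-3)

    def test_nowhere_positive_rejected(self):
        t = uniform_grid(0.8, 1e-3)
        with pytest.raises(ValueError):
            dp_mean(TimeTrace(t, -np.ones(len(t))))


class TestCycleStats:
    def test_identical_cycles_zero_sd(self):
        m, s = inter_cycle_stats(np.array([140.0, 140.0, 140.0]))
        assert (m, s) == (140.0, 0.0)

    def test_two_cycle_hand_formula(self):
        m, s = inter_cycle_stats(np.array([140.0, 160.0]))
        assert m == 150.0
        assert s == pytest.approx(14.142, abs=1e-3)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_two_pass_oracle(self, values):
        arr = np.array(values)
        m, s = inter_cycle_stats(arr)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert m == pytest.approx(mean, abs=1e-6)
        assert s == pytest.approx(np.sqrt(var), abs=1e-6)


class TestUncertaintyBounds:
    def test_table_value_137(self):
        lo, hi = uncertainty_bounds(137.0)
        assert (lo, hi) == (pytest.approx(123.3), pytest.approx(150.7))

    @given(st.floats(0.1, 1e4), st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_width_is_twice_frac_times_value(self, value, frac):
        # subtraction cancels catastrophically for tiny frac, so the check
        # is absolute at the rounding scale of `value`
        lo, hi = uncertainty_bounds(value, frac)
        assert hi - lo == pytest.approx(2 * frac * value, rel=1e-9, abs=1e-12 * value)
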