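"""Closed-loop regulation blocks: spike detection, rate estimation, the
sample-and-hold PID, the gated voltage hold, the sliding probability
estimate, PI stimulus-intensity control and PSP amplitude measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clamploop import controllers as ctl
from clamploop.engine import run_fixed_step
from clamploop.protocols import ProtocolConfig, make_fixture, run_protocol
from clamploop.trace import Trace


class TestSpikeDetection:
    def test_subthreshold_trace_empty(self):
        tr = Trace(dt=1e-4, values=np.full(1000, -70e-3), unit="V")
        assert len(ctl.detect_spikes(tr, ctl.SpikeDetectorParams())) == 0

    def test_three_constructed_crossings(self):
        dt = 1e-4
        v = np.full(3000, -70e-3)
        for i0 in (500, 1000, 1500):  # 50 ms apart
            v[i0 : i0 + 10] = 0.0
        tr = Trace(dt=dt, values=v, unit="V")
        times = ctl.detect_spikes(tr, ctl.SpikeDetectorParams(threshold=-20e-3))
        np.testing.assert_allclose(times, [0.05, 0.10, 0.15])

    def test_sinusoid_crossing_rate(self):
        # 100 Hz sinusoid through threshold -> 100 events per second
        dt = 1e-4
        t = dt * np.arange(10000)
        v = -40e-3 + 30e-3 * np.sin(2 * math.pi * 100.0 * t)
        tr = Trace(dt=dt, values=v, unit="V")
        times = ctl.detect_spikes(tr, ctl.SpikeDetectorParams(threshold=-20e-3))
        assert len(times) == 100

    def test_detection_window_restricts(self):
        dt = 1e-4
        v = np.full(3000, -70e-3)
        v[500:510] = 0.0
        v[2500:2510] = 0.0
        tr = Trace(dt=dt, values=v, unit="V")
        times = ctl.detect_spikes(
            tr, ctl.SpikeDetectorParams(threshold=-20e-3, window=(0.0, 0.1))
        )
        assert len(times) == 1


class TestRateEstimator:
    def test_fixed_point_at_inverse_isi(self):
        s = ctl.RateEstimatorState(tau_r=1.0, r=10.0, last_spike_time=0.0)
        ctl.update_rate_estimate(s, 0.1)
        assert s.r == pytest.approx(10.0)

    def test_geometric_convergence_to_10Hz(self):
        # constant 100 ms ISI from r=0: within 1% of 10 Hz after 5 s
        s = ctl.RateEstimatorState(tau_r=1.0)
        for k in range(51):
            ctl.update_rate_estimate(s, 0.1 * k)
        assert s.r == pytest.approx(10.0, rel=0.01)

    def test_long_isi_washes_out_memory(self):
        s = ctl.RateEstimatorState(tau_r=0.1, r=50.0, last_spike_time=0.0)
        ctl.update_rate_estimate(s, 2.0)  # isi = 2 s >> tau_r
        assert s.r == pytest.approx(0.5, rel=1e-6)

    def test_non_increasing_spike_time_rejected(self):
        s = ctl.RateEstimatorState(last_spike_time=1.0)
        with pytest.raises(ValueError):
            ctl.update_rate_estimate(s, 0.5)


class TestFiringRateClampStep:
    def test_zero_error_holds_constant(self):
        pid = ctl.PIDParams(P=0.01, I=0.01, bias=1e-10)
        s = ctl.FiringRateClampState(held_output=pid.bias)
        outs = {ctl.firing_rate_clamp_step(pid, s, 17.0, 17.0, ev) for ev in (True, False, True)}
        assert outs == {pid.bias}

    def test_p_only_single_event_increments_by_Pe(self):
        pid = ctl.PIDParams(P=0.01, I=0.0, D=0.0, output_scale=1e-9)
        s = ctl.FiringRateClampState()
        out = ctl.firing_rate_clamp_step(pid, s, 17.0, 12.0, True)
        assert out == pytest.approx(1e-9 * 0.01 * 5.0)

    def test_sample_and_hold_between_events(self):
        pid = ctl.PIDParams(P=0.01, I=0.005)
        s = ctl.FiringRateClampState()
        first = ctl.firing_rate_clamp_step(pid, s, 17.0, 10.0, True)
        for _ in range(100):
            assert ctl.firing_rate_clamp_step(pid, s, 17.0, 99.0, False) == first

    def test_output_limit_saturation_reported(self):
        pid = ctl.PIDParams(P=1.0, I=0.0, output_scale=1.0, output_limits=(-1.0, 1.0))
        s = ctl.FiringRateClampState()
        out = ctl.firing_rate_clamp_step(pid, s, 100.0, 0.0, True)
        assert out == 1.0 and s.saturated == 1


class TestVoltageHold:
    def test_zero_error_constant_output(self):
        pid = ctl.PIDParams(P=10.0, I=100.0, output_scale=1e-9)
        s = ctl.VoltageHoldState()
        o1 = ctl.voltage_hold_step(pid, s, -0.06, -0.06, True, 1e-4)
        o2 = ctl.voltage_hold_step(pid, s, -0.06, -0.06, True, 1e-4)
        assert o1 == o2 == 0.0

    def test_gate_closed_freezes_output_and_integral(self):
        pid = ctl.PIDParams(P=10.0, I=100.0, output_scale=1e-9)
        s = ctl.VoltageHoldState(held_output=3e-10, EI=1.0)
        for _ in range(10):
            assert ctl.voltage_hold_step(pid, s, -0.06, -0.08, False, 1e-4) == 3e-10
        assert s.EI == 1.0

    def test_closed_loop_settles_on_passive_preparation(self):
        # P=10, I=100 (V error -> nA): within 0.5 mV of -60 mV in < 2 s
        res = run_protocol(
            ProtocolConfig(protocol="voltage_hold", duration=2.0, dt=5e-5, seed=1)
        )
        v = res.logs["neuron.V"].values
        assert abs(v[-1] - (-60e-3)) < 0.5e-3
        assert res.summary["final_error"] < 0.5e-3


class TestProbabilityEstimate:
    def test_fixed_point(self):
        s = ctl.ProbabilityState(tau=600.0, ISI=3.0, p=1.0)
        ctl.update_response_probability(s, 1.0)
        assert s.p == pytest.approx(1.0)

    def test_first_update_from_zero_reference_value(self):
        # ISI = 3 s, tau = 600 s, F = 1 -> p1 = 1 - e^-0.005
        s = ctl.ProbabilityState(tau=600.0, ISI=3.0, p=0.0)
        ctl.update_response_probability(s, True)
        assert s.p == pytest.approx(1.0 - math.exp(-0.005))
        assert s.p == pytest.approx(0.0049875, abs=1e-7)

    def test_monotone_limits(self):
        up = ctl.ProbabilityState(tau=100.0, ISI=4.0, p=0.2)
        last = up.p
        for _ in range(50):
            ctl.update_response_probability(up, True)
            assert up.p >= last
            last = up.p
        down = ctl.ProbabilityState(tau=100.0, ISI=4.0, p=0.8)
        last = down.p
        for _ in range(50):
            ctl.update_response_probability(down, False)
            assert down.p <= last
            last = down.p

    def test_geometric_convergence_rate(self):
        # with constant F = f the deviation shrinks by exp(-ISI/tau) per stimulus
        s = ctl.ProbabilityState(tau=50.0, ISI=5.0, p=0.0)
        w = math.exp(-5.0 / 50.0)
        f = 1.0
        expected = 0.0
        for _ in range(30):
            ctl.update_response_probability(s, f)
            expected = expected * w + f * (1 - w)
            assert s.p == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=500))
    def test_convex_combination_stays_in_unit_interval(self, responses):
        s = ctl.ProbabilityState(tau=600.0, ISI=4.0, p=0.5)
        for r in responses:
            ctl.update_response_probability(s, r)
            assert 0.0 <= s.p <= 1.0


class TestStimulusIntensity:
    def test_zero_errors_return_offset(self):
        s = ctl.StimulusControllerState(S_1=100.0, G=700.0)
        assert ctl.next_stimulus_intensity(s, s.target) == 100.0

    def test_reference_gain_arithmetic(self):
        # G=700, P=1, I=0.3, EP=0.1, EI0=0 -> S1 + 700*(0.1 + 0.03) = S1 + 91
        s = ctl.StimulusControllerState(S_1=100.0, G=700.0, P_pid=1.0, I_pid=0.3, target=0.5)
        out = ctl.next_stimulus_intensity(s, 0.4)
        assert out == pytest.approx(100.0 + 91.0)

    def test_steady_state_holds_with_accumulated_integral(self):
        s = ctl.StimulusControllerState(S_1=100.0, G=700.0, P_pid=1.0, I_pid=0.3, target=0.5, EI=0.2)
        outs = {ctl.next_stimulus_intensity(s, 0.5) for _ in range(5)}
        assert outs == {100.0 + 700.0 * 0.3 * 0.2}

    def test_bounds_clipping_counted(self):
        s = ctl.StimulusControllerState(S_1=100.0, G=700.0, bounds=(0.0, 120.0), target=0.5)
        out = ctl.next_stimulus_intensity(s, 0.0)
        assert out == 120.0 and s.clipped == 1


class TestBiphasicPulse:
    def test_charge_balance(self):
        spec = ctl.BiphasicPulseSpec(amplitude=1e-4, phase_width=200e-6)
        wf = spec.waveform(dt=1e-5)
        assert len(wf) == 40
        assert wf.sum() == pytest.approx(0.0)
        assert wf[0] > 0  # positive phase first


class TestPSPAmplitude:
    def test_flat_segment_zero(self):
        fx = make_fixture("psp_segments", {"amplitude": 0.0, "n_segments": 1}, seed=0)
        amp = ctl.measure_psp_amplitude(fx["segments"][0], 10e-3, 100e-3, "positive")
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_half_millivolt_bump_within_1pct(self):
        fx = make_fixture("psp_segments", {"amplitude": 0.5e-3, "n_segments": 1}, seed=0)
        amp = ctl.measure_psp_amplitude(fx["segments"][0], 10e-3, 100e-3, "positive")
        assert amp == pytest.approx(0.5e-3, rel=0.01)

    def test_baseline_drift_error_below_5pct(self):
        fx = make_fixture(
            "psp_segments",
            {"amplitude": 0.5e-3, "baseline_drift": 1e-3, "n_segments": 1},
            seed=0,
        )
        amp = ctl.measure_psp_amplitude(fx["segments"][0], 10e-3, 100e-3, "positive")
        assert amp == pytest.approx(0.5e-3, rel=0.05)

    def test_window_outside_segment_rejected(self):
        fx = make_fixture("psp_segments", {"n_segments": 1}, seed=0)
        with pytest.raises(ValueError):
            ctl.measure_psp_amplitude(fx["segments"][0], 50e-3, 100e-3, "positive")
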