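"""Simulated preparations: integrate-and-fire family, conductance-based
models, TM synapse and electrode, against closed-form or limit-case oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clamploop import preparations as prep


def run_point(params, I, duration, dt):
    st_ = prep.init_state(params)
    spikes = []
    for n in range(int(round(duration / dt))):
        st_, s = prep.step_point_neuron(params, st_, I, dt)
        if s:
            spikes.append(n * dt)
    return st_, spikes


class TestPointNeurons:
    def test_lif_rest_is_fixed_point(self):
        p = prep.PointNeuronParams(model_kind="LIF")
        st_, spikes = run_point(p, 0.0, 0.1, 1e-4)
        assert st_.V == p.E_L and not spikes

    @pytest.mark.parametrize("I", [0.25e-9, 0.3e-9, 0.4e-9])
    def test_lif_rate_matches_closed_form(self, I):
        # constant current above rheobase g_L*(V_th - E_L) = 0.2 nA
        p = prep.PointNeuronParams(model_kind="LIF")
        _, spikes = run_point(p, I, 2.0, 1e-5)
        rate = len(spikes) / 2.0
        assert rate == pytest.approx(prep.lif_fi_rate(p, I), rel=0.02)

    def test_aeif_with_zero_adaptation_matches_exp_if_oracle(self):
        # separately coded exponential-IF Euler oracle, step-for-step
        p = prep.PointNeuronParams(model_kind="aEIF", a=0.0, b=0.0)
        dt, I = 2e-5, 0.35e-9
        st_ = prep.init_state(p)
        v_oracle, ref = p.E_L, 0.0
        for _ in range(20000):
            st_, spike = prep.step_point_neuron(p, st_, I, dt)
            if ref > 0:
                ref -= dt
            else:
                dv = (
                    -p.g_L * (v_oracle - p.E_L)
                    + p.g_L * p.delta_T * math.exp(min((v_oracle - p.V_thresh) / p.delta_T, 30.0))
                    + I
                ) / p.C
                v_new = v_oracle + dt * dv
                if v_new >= p.V_thresh + 5 * p.delta_T:
                    v_new, ref = p.V_reset, p.t_ref
                v_oracle = v_new
            assert st_.V == v_oracle

    def test_qif_fires_above_critical_current(self):
        p = prep.make_preparation("qif")
        _, quiet = run_point(p, 0.0, 0.5, 1e-5)
        _, firing = run_point(p, 0.3e-9, 0.5, 1e-5)
        assert not quiet and len(firing) > 5

    def test_refractory_pauses_integration(self):
        p = prep.PointNeuronParams(model_kind="LIF", t_ref=5e-3)
        _, spikes = run_point(p, 0.5e-9, 1.0, 1e-5)
        isis = np.diff(spikes)
        assert np.all(isis >= p.t_ref - 1e-9)

    def test_fi_monotonicity_all_point_models(self):
        for kind in ("LIF", "QIF", "aEIF"):
            p = prep.make_preparation(
                {"LIF": "lif", "QIF": "qif", "aEIF": "l5_aeif"}[kind]
            )
            rates = [
                len(run_point(p, I, 1.0, 2e-5)[1])
                for I in (0.0, 0.2e-9, 0.35e-9, 0.5e-9)
            ]
            assert all(b >= a for a, b in zip(rates, rates[1:])), (kind, rates)


def run_cond(params, I, duration, dt):
    st_ = prep.init_state(params)
    spikes, vs = [], []
    for n in range(int(round(duration / dt))):
        st_, s = prep.step_conductance_neuron(params, st_, I, dt)
        vs.append(st_.V)
        if s:
            spikes.append(n * dt)
    return np.array(vs), spikes


class TestConductanceNeurons:
    @pytest.mark.parametrize("name", ["hh", "rtm"])
    def test_rest_stable_within_1mV_over_1s(self, name):
        p = prep.make_preparation(name)
        v0 = prep.init_state(p).V
        vs, spikes = run_cond(p, 0.0, 1.0, 2e-5)
        assert not spikes
        assert np.abs(vs - v0).max() < 1e-3

    @pytest.mark.parametrize(
        "name,currents", [("hh", (1e-9, 2e-9, 3e-9, 4e-9)), ("rtm", (0.3e-9, 0.6e-9, 1e-9, 2e-9))]
    )
    def test_rate_monotone_in_current(self, name, currents):
        p = prep.make_preparation(name)
        rates = [len(run_cond(p, I, 1.0, 1e-5)[1]) for I in currents]
        assert rates[-1] > 10
        assert all(b >= a for a, b in zip(rates, rates[1:])), rates

    def test_dt_convergence_rms_below_1pct(self):
        p = prep.make_preparation("hh")
        v1, _ = run_cond(p, 1.5e-9, 1.0, 2e-5)
        v2, _ = run_cond(p, 1.5e-9, 1.0, 1e-5)
        rms1 = np.sqrt(np.mean((v1 - v1.mean()) ** 2))
        rms2 = np.sqrt(np.mean((v2[::2] - v2[::2].mean()) ** 2))
        assert abs(rms1 - rms2) / rms2 < 0.01

    def test_gating_blowup_aborts(self):
        p = prep.make_preparation("hh")
        st_ = prep.init_state(p)
        with pytest.raises(FloatingPointError, match="gating"):
            for _ in range(10000):
                st_, _ = prep.step_conductance_neuron(p, st_, 5e-9, 5e-4)


class TestTMSynapse:
    def test_no_spikes_output_decays_with_tau_syn(self):
        p = prep.TMSynapseParams(A=1e-9, tau_syn=5e-3)
        s = prep.PreparationState(psc=1e-9, u=p.U, x=1.0)
        s, out = prep.step_tm_synapse(p, s, False, 5e-3)
        assert out == pytest.approx(1e-9 * math.exp(-1.0))

    def test_first_spike_amplitude_is_AU(self):
        p = prep.TMSynapseParams(U=0.4, A=2e-9)
        s = prep.PreparationState(u=0.0, x=1.0, psc=0.0)
        s, out = prep.step_tm_synapse(p, s, True, 1e-6)
        assert out == pytest.approx(p.A * p.U, rel=1e-5)

    def test_depression_steady_state_matches_closed_form(self):
        # regular 20 Hz train, no facilitation: fixed point of the TM map
        p = prep.TMSynapseParams(U=0.5, tau_rec=0.5, tau_facil=0.0, A=1e-9, tau_syn=3e-3)
        s = prep.PreparationState(u=0.0, x=1.0, psc=0.0)
        dt, isi = 1e-4, 0.05
        steps = int(isi / dt)
        amp = None
        for _ in range(400):  # 20 s of 20 Hz
            for k in range(steps):
                pre = k == steps - 1
                psc_before = s.psc * math.exp(-dt / p.tau_syn)
                s, out = prep.step_tm_synapse(p, s, pre, dt)
                if pre:
                    amp = out - psc_before
        expected = prep.tm_depression_fixed_point(p, isi)
        assert amp == pytest.approx(expected, rel=1e-6)

    def test_facilitation_increases_second_amplitude(self):
        p = prep.TMSynapseParams(U=0.2, tau_rec=0.1, tau_facil=0.5, A=1e-9, tau_syn=2e-3)
        s = prep.PreparationState(u=0.0, x=1.0, psc=0.0)
        amps = []
        dt, steps = 1e-4, 200  # 20 ms ISI
        for _ in range(2):
            for k in range(steps):
                pre = k == steps - 1
                before = s.psc * math.exp(-dt / p.tau_syn)
                s, out = prep.step_tm_synapse(p, s, pre, dt)
                if pre:
                    amps.append(out - before)
        assert amps[1] > amps[0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=300),
        st.floats(0.05, 1.0),
        st.floats(0.0, 0.5),
    )
    def test_resources_stay_in_unit_interval(self, train, U, tau_facil):
        p = prep.TMSynapseParams(U=U, tau_rec=0.2, tau_facil=tau_facil, A=1e-9, tau_syn=3e-3)
        s = prep.PreparationState(u=0.0, x=1.0, psc=0.0)
        for pre in train:
            s, _ = prep.step_tm_synapse(p, s, pre, 1e-3)
            assert 0.0 <= s.x <= 1.0
            assert 0.0 <= s.u <= 1.0


class TestElectrode:
    def test_zero_current_passthrough(self):
        p = prep.ElectrodeParams(R_s=10e6, C_e=1e-12)
        s = prep.PreparationState()
        s, v = prep.step_electrode(p, s, 0.0, -0.07, 5e-5)
        assert v == -0.07

    def test_pure_resistor_ohms_law(self):
        # C_e = 0, R_s = 10 MOhm, I = 100 pA -> exactly 1 mV offset
        p = prep.ElectrodeParams(R_s=10e6, C_e=0.0)
        s = prep.PreparationState()
        s, v = prep.step_electrode(p, s, 100e-12, -0.07, 5e-5)
        assert v == pytest.approx(-0.07 + 1e-3)

    def test_rc_step_response_time_constant(self):
        # step relaxes to R_s*I with tau = R_s*C_e (exact exponential update)
        R_s, C_e, I = 10e6, 100e-12, 100e-12
        tau = R_s * C_e
        p = prep.ElectrodeParams(R_s=R_s, C_e=C_e)
        s = prep.PreparationState()
        dt = 1e-5
        offs = []
        for n in range(1000):
            s, v = prep.step_electrode(p, s, I, 0.0, dt)
            offs.append(v)
        offs = np.array(offs)
        t = dt * (1 + np.arange(1000))
        expected = R_s * I * (1 - np.exp(-t / tau))
        assert np.max(np.abs(offs - expected)) < 0.01 * R_s * I
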