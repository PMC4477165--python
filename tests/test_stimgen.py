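"""Signal synthesis: diffusion moments, OU statistics, rate modulation, the
dynamic-clamp law, the E/I balance solver and waveform compilation."""

import math

import numpy as np
import pytest

from clamploop import stimgen
from clamploop.stimgen import (
    OUProcessParams,
    RateModulationParams,
    Segment,
    SynapticChannelParams,
    WaveformSpec,
    balance_inhibitory_rate,
    compile_waveform,
    conductance_to_current,
    diffusion_moments,
    modulated_rate,
    ou_step,
    sum_waveforms,
)


class TestDiffusionMoments:
    def test_zero_rate_gives_zero_moments(self):
        assert diffusion_moments(1e-9, 10e-3, 0.0) == (0.0, 0.0)

    def test_reference_example_values(self):
        G_bar, G_S = diffusion_moments(1e-9, 10e-3, 1000.0)
        assert G_bar == pytest.approx(10e-9)
        assert G_S == pytest.approx(2.236e-9, rel=1e-3)

    def test_canonical_excitatory_condition_mean(self):
        # g_e = 0.2 nS, tau_e = 5 ms, R_e = 7000 Hz -> mean 7 nS (2% of the
        # 10 nS resting conductance scaled by tau*R)
        G_bar, _ = diffusion_moments(0.2e-9, 5e-3, 7000.0)
        assert G_bar == pytest.approx(7e-9)

    def test_moments_match_long_ou_run(self):
        g, tau, R = 0.2e-9, 5e-3, 7000.0
        G_bar, G_S = diffusion_moments(g, tau, R)
        p = OUProcessParams(G_bar=G_bar, G_S=G_S, tau=tau)
        dt, n = 5e-5, 1_000_000  # 50 s
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(n)
        out = np.empty(n)
        G = G_bar
        for i in range(n):
            G = ou_step(p, G, dt, draws[i])
            out[i] = G
        assert out.mean() == pytest.approx(G_bar, rel=0.01)
        assert out.std() == pytest.approx(G_S, rel=0.03)


class TestOUStep:
    def test_deterministic_fixed_point(self):
        p = OUProcessParams(G_bar=5e-9, G_S=0.0, tau=5e-3)
        assert ou_step(p, 5e-9, 1e-4, 0.123) == pytest.approx(5e-9)

    def test_single_deterministic_euler_step_from_zero(self):
        p = OUProcessParams(G_bar=5e-9, G_S=1e-9, tau=5e-3)
        dt = 1e-4
        assert ou_step(p, 0.0, dt, 0.0) == pytest.approx(dt * 5e-9 / 5e-3)

    def test_diffusion_coefficient_tied_to_moments(self):
        p = OUProcessParams(G_bar=1e-9, G_S=2e-9, tau=10e-3)
        assert p.D == pytest.approx(4e-18 / 10e-3)


class TestModulatedRate:
    def test_at_time_zero_returns_offset(self):
        p = RateModulationParams(R0=7000.0, R1=700.0, omega=2 * math.pi * 1.0)
        assert modulated_rate(p, 0.0) == 7000.0

    def test_zero_amplitude_constant(self):
        p = RateModulationParams(R0=7000.0, R1=0.0, omega=5.0)
        assert modulated_rate(p, 1.234) == 7000.0

    def test_quarter_cycle_peak_with_10pct_modulation(self):
        p = RateModulationParams(R0=7000.0, R1=700.0, omega=1.0)
        assert modulated_rate(p, math.pi / 2) == pytest.approx(7700.0)

    def test_negative_rate_configuration_rejected(self):
        with pytest.raises(ValueError):
            RateModulationParams(R0=100.0, R1=200.0, omega=1.0)


class TestConductanceToCurrent:
    def test_zero_conductance_zero_current(self):
        assert conductance_to_current(0.0, 0.0, -0.06) == 0.0

    def test_at_reversal_potential(self):
        assert conductance_to_current(5e-9, 0.0, 0.0, E_e=0.0) == 0.0

    def test_reference_arithmetic_example(self):
        # G_e = 7 nS, G_i = 10 nS, V = -60 mV -> 0.42 - 0.2 = 0.22 nA
        I = conductance_to_current(7e-9, 10e-9, -60e-3, E_e=0.0, E_i=-80e-3)
        assert I == pytest.approx(0.22e-9)

    def test_negative_excursions_clipped_at_injection(self):
        assert conductance_to_current(-5e-9, -1e-9, -0.06) == 0.0


class TestBalanceSolver:
    def exc_inh(self):
        return stimgen.default_channels()

    def test_balance_at_excitatory_reversal_is_zero(self):
        exc, inh = self.exc_inh()
        assert balance_inhibitory_rate(0.0, exc, inh, -50e-3) == 0.0

    def test_canonical_pair_7000_to_2149(self):
        exc, inh = self.exc_inh()
        R_i = balance_inhibitory_rate(7000.0, exc, inh, -51.85e-3)
        assert R_i == pytest.approx(2149.0, abs=1.0)

    @pytest.mark.parametrize("R_e", [1000.0, 7000.0, 21000.0])
    def test_balance_residual_below_1e15_A(self, R_e):
        exc, inh = self.exc_inh()
        V_b = -51.85e-3
        R_i = balance_inhibitory_rate(R_e, exc, inh, V_b)
        Ge = exc.g * exc.tau * R_e
        Gi = inh.g * inh.tau * R_i
        residual = Ge * (exc.E - V_b) + Gi * (inh.E - V_b)
        assert abs(residual) < 1e-15

    def test_balance_potential_outside_reversals_rejected(self):
        exc, inh = self.exc_inh()
        with pytest.raises(ValueError):
            balance_inhibitory_rate(7000.0, exc, inh, -90e-3)


class TestWaveforms:
    def test_constant_segment(self):
        spec = WaveformSpec([Segment("constant", 1.0, {"value": 1e-10})], unit="A")
        tr = compile_waveform(spec, 1e-3)
        assert len(tr) == 1000
        assert np.all(tr.values == 1e-10)

    def test_ramp_endpoints_and_monotonicity(self):
        spec = WaveformSpec([Segment("ramp", 1.0, {"start": 0.0, "stop": 1e-10})])
        tr = compile_waveform(spec, 1e-3)
        assert tr.values[0] == 0.0
        assert tr.values[-1] == pytest.approx(1e-10)
        assert np.all(np.diff(tr.values) > 0)

    def test_concatenation_lengths_sum_exactly(self):
        spec = WaveformSpec(
            [
                Segment("constant", 0.25, {"value": 0.0}),
                Segment("pulse", 0.5, {"amplitude": 1e-10, "width": 0.1}),
                Segment("constant", 0.25, {"value": 0.0}),
            ]
        )
        assert len(compile_waveform(spec, 1e-3)) == 1000

    def test_sum_of_sinusoids_is_samplewise_addition(self):
        s1 = WaveformSpec([Segment("sinusoid", 1.0, {"amplitude": 1.0, "frequency": 3.0})])
        s2 = WaveformSpec([Segment("sinusoid", 1.0, {"amplitude": 0.5, "frequency": 7.0})])
        both = WaveformSpec(
            [
                Segment("sinusoid", 1.0, {"amplitude": 1.0, "frequency": 3.0}),
            ]
        )
        t1 = compile_waveform(s1, 1e-3)
        t2 = compile_waveform(s2, 1e-3)
        total = sum_waveforms(t1, t2)
        np.testing.assert_allclose(total.values, t1.values + t2.values)

    def test_ou_segment_deterministic_per_seed(self):
        spec = WaveformSpec(
            [Segment("ou_noise", 0.2, {"mean": 1e-9, "sd": 2e-10, "tau": 5e-3})]
        )
        a = compile_waveform(spec, 1e-4, seed=9)
        b = compile_waveform(spec, 1e-4, seed=9)
        c = compile_waveform(spec, 1e-4, seed=10)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_waveform_file_roundtrip(self, tmp_path):
        spec = WaveformSpec([Segment("ramp", 0.1, {"start": 0.0, "stop": 1e-10})], unit="A")
        tr = compile_waveform(spec, 1e-3)
        path = tmp_path / "wf.tsv"
        stimgen.write_waveform_file(path, tr)
        back = stimgen.read_waveform_file(path)
        assert back.unit == "A"
        np.testing.assert_allclose(back.values, tr.values, rtol=1e-6)


class TestNonStationaryConsistency:
    def test_slowly_modulated_ou_tracks_quasi_static_moments(self):
        """Per-step OU target moments follow R(t) under slow modulation."""
        from clamploop.blocks import OUConductance
        from clamploop.engine import BlockGraph, run_fixed_step

        g, tau, R0 = 0.2e-9, 5e-3, 7000.0
        f_mod = 0.5  # Hz: modulation period >> tau -> quasi-stationary
        blk = OUConductance(
            "ou", g=g, tau=tau, R=R0, R1=0.1 * R0, omega=2 * math.pi * f_mod
        )
        graph = BlockGraph([blk], [], log=["ou.G"])
        dt, T = 5e-5, 40.0
        logs = run_fixed_step(graph, T, dt, seed=21)
        G = logs["ou.G"].values
        t = dt * np.arange(len(G))
        # fold on the modulation period and compare binned means with g*tau*R(t)
        phase = np.mod(t, 1.0 / f_mod)
        bins = np.linspace(0, 1.0 / f_mod, 9)
        idx = np.digitize(phase, bins) - 1
        measured = np.array([G[idx == k].mean() for k in range(8)])
        centers = 0.5 * (bins[:-1] + bins[1:])
        expected = g * tau * (R0 + 0.1 * R0 * np.sin(2 * math.pi * f_mod * centers))
        np.testing.assert_allclose(measured, expected, rtol=0.05)
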