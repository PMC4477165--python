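"""Engine-facing blocks wrapping the preparations, stimgen, aec and
controllers primitives.

Each block is a thin adapter exposing typed ports to the fixed-step engine;
the science lives in the modules it wraps.  ``BLOCK_REGISTRY`` maps the
configuration ``kind`` names to constructors (all parameters SI).
"""

from __future__ import annotations

import math

import numpy as np

from . import controllers, preparations, stimgen
from .aec import AECState, Kernel, compensate_online
from .engine import Block
from .trace import Trace

_NOISE_CHUNK = 1 << 14


class ConstantSource(Block):
    out_ports = ("y",)

    def __init__(self, name: str, value: float = 0.0, unit: str = "1"):
        super().__init__(name)
        self.value = float(value)
        self.port_units = {"y": unit}

    def step(self, t, inputs):
        return {"y": self.value}


class WaveformSource(Block):
    """Plays a pre-compiled :class:`Trace` sample by sample (holds the last
    sample once exhausted)."""

    out_ports = ("y",)

    def __init__(self, name: str, trace: Trace):
        super().__init__(name)
        self.trace = trace
        self.port_units = {"y": trace.unit}

    def reset(self, dt, rng):
        if not math.isclose(dt, self.trace.dt):
            raise ValueError(
                f"waveform dt {self.trace.dt} does not match engine dt {dt}"
            )
        self._i = 0
        self._v = self.trace.values
        self._n = len(self._v)

    def step(self, t, inputs):
        i = self._i
        if i < self._n:
            self._i = i + 1
            return {"y": float(self._v[i])}
        return {"y": float(self._v[-1]) if self._n else 0.0}


class SineSource(Block):
    """offset + amplitude * sin(omega*t + phase)."""

    out_ports = ("y",)

    def __init__(self, name: str, offset=0.0, amplitude=0.0, omega=0.0, phase=0.0, unit="1"):
        super().__init__(name)
        self.offset, self.amplitude = float(offset), float(amplitude)
        self.omega, self.phase = float(omega), float(phase)
        self.port_units = {"y": unit}

    def step(self, t, inputs):
        return {"y": self.offset + self.amplitude * math.sin(self.omega * t + self.phase)}


class Gain(Block):
    in_ports = ("u",)
    out_ports = ("y",)

    def __init__(self, name: str, gain: float = 1.0):
        super().__init__(name)
        self.gain = float(gain)

    def step(self, t, inputs):
        return {"y": self.gain * inputs["u"]}


class Adder(Block):
    """Three-input adder; unwired inputs are declared constants (usually 0)."""

    in_ports = ("a", "b", "c")
    out_ports = ("y",)

    def step(self, t, inputs):
        return {"y": inputs["a"] + inputs["b"] + inputs["c"]}


class OUConductance(Block):
    """Ornstein-Uhlenbeck background conductance for one synaptic channel.

    Construct from a virtual presynaptic population (g, tau, R) via the
    diffusion approximation.  Optional sinusoidal modulation of the rate
    R(t) = R0 + R1*sin(omega*t + phase): with ``filter_modulation`` (the
    default) the per-step target moments track R(t) through the OU
    relaxation, i.e. the modulation is low-passed by the synaptic time
    constant; without it the mean modulation is added directly to the
    stationary process, bypassing the synaptic filter.
    """

    out_ports = ("G",)
    stochastic = True

    def __init__(
        self,
        name: str,
        g: float,
        tau: float,
        R: float,
        R1: float = 0.0,
        omega: float = 0.0,
        phase: float = 0.0,
        filter_modulation: bool = True,
    ):
        super().__init__(name)
        self.channel = stimgen.SynapticChannelParams(g=g, tau=tau, R=R, E=0.0)
        self.mod = (
            stimgen.RateModulationParams(R0=R, R1=R1, omega=omega, phase=phase)
            if R1 > 0.0
            else None
        )
        self.filter_modulation = bool(filter_modulation)
        self.port_units = {"G": "S"}

    def reset(self, dt, rng):
        self._dt = dt
        self._rng = rng
        self._draws = np.empty(0)
        self._i = 0
        g, tau = self.channel.g, self.channel.tau
        self._base = stimgen.OUProcessParams(*stimgen.diffusion_moments(g, tau, self.channel.R), tau=tau)
        self._G = self._base.G_bar

    def _draw(self) -> float:
        if self._i >= len(self._draws):
            self._draws = self._rng.standard_normal(_NOISE_CHUNK)
            self._i = 0
        v = self._draws[self._i]
        self._i += 1
        return float(v)

    def step(self, t, inputs):
        g, tau = self.channel.g, self.channel.tau
        if self.mod is None:
            self._G = stimgen.ou_step(self._base, self._G, self._dt, self._draw())
            return {"G": self._G}
        R_t = stimgen.modulated_rate(self.mod, t)
        if self.filter_modulation:
            G_bar, G_S = stimgen.diffusion_moments(g, tau, R_t)
            params = stimgen.OUProcessParams(G_bar=G_bar, G_S=G_S, tau=tau)
            self._G = stimgen.ou_step(params, self._G, self._dt, self._draw())
            return {"G": self._G}
        self._G = stimgen.ou_step(self._base, self._G, self._dt, self._draw())
        offset = g * tau * (R_t - self.mod.R0)
        return {"G": self._G + offset}


class DynamicClamp(Block):
    """Conductance-to-current law, recomputed from the instantaneous
    (compensated) membrane potential every step."""

    in_ports = ("G_e", "G_i", "V")
    out_ports = ("I",)

    def __init__(self, name: str, E_e: float = 0.0, E_i: float = -80e-3):
        super().__init__(name)
        self.E_e, self.E_i = float(E_e), float(E_i)
        self.port_units = {"I": "A"}

    def step(self, t, inputs):
        return {
            "I": stimgen.conductance_to_current(
                inputs["G_e"], inputs["G_i"], inputs["V"], self.E_e, self.E_i
            )
        }


class PointNeuron(Block):
    """Integrate-and-fire preparation; emits V and a 0/1 spike flag."""

    in_ports = ("I",)
    out_ports = ("V", "spike")

    def __init__(self, name: str, params: preparations.PointNeuronParams | None = None, **overrides):
        super().__init__(name)
        if params is None:
            prep = overrides.pop("preparation", "l5_aeif")
            params = preparations.make_preparation(prep, **overrides)
        self.params = params
        self.port_units = {"V": "V", "spike": "1"}

    def reset(self, dt, rng):
        self._dt = dt
        self.state = preparations.init_state(self.params)

    def step(self, t, inputs):
        self.state, spike = preparations.step_point_neuron(
            self.params, self.state, inputs["I"], self._dt
        )
        if spike:
            self.state.last_spike_time = t
        return {"V": self.state.V, "spike": 1.0 if spike else 0.0}


class ConductanceNeuron(Block):
    in_ports = ("I",)
    out_ports = ("V", "spike")

    def __init__(self, name: str, params: preparations.ConductanceNeuronParams | None = None, **overrides):
        super().__init__(name)
        if params is None:
            prep = overrides.pop("preparation", "hh")
            params = preparations.make_preparation(prep, **overrides)
        self.params = params
        self.port_units = {"V": "V", "spike": "1"}

    def reset(self, dt, rng):
        self._dt = dt
        self.state = preparations.init_state(self.params)

    def step(self, t, inputs):
        self.state, spike = preparations.step_conductance_neuron(
            self.params, self.state, inputs["I"], self._dt
        )
        return {"V": self.state.V, "spike": 1.0 if spike else 0.0}


class TMSynapse(Block):
    """Tsodyks-Markram synapse: presynaptic spike flag in, PSC out."""

    in_ports = ("spike",)
    out_ports = ("psc",)

    def __init__(self, name: str, params: preparations.TMSynapseParams | None = None, **overrides):
        super().__init__(name)
        self.params = params if params is not None else preparations.TMSynapseParams(**overrides)
        self.port_units = {"psc": "A"}

    def reset(self, dt, rng):
        self._dt = dt
        self.state = preparations.PreparationState(u=0.0, x=1.0, psc=0.0)

    def step(self, t, inputs):
        self.state, psc = preparations.step_tm_synapse(
            self.params, self.state, inputs["spike"] > 0.5, self._dt
        )
        return {"psc": psc}


class Electrode(Block):
    """Patch-pipette RC stand-in: recorded potential = V_m + electrode drop."""

    in_ports = ("I", "V_m")
    out_ports = ("V_rec",)

    def __init__(self, name: str, params: preparations.ElectrodeParams | None = None, **overrides):
        super().__init__(name)
        self.params = params if params is not None else preparations.ElectrodeParams(**overrides)
        self.port_units = {"V_rec": "V"}

    def reset(self, dt, rng):
        self._dt = dt
        self.state = preparations.PreparationState(V_e=0.0)

    def step(self, t, inputs):
        self.state, v_rec = preparations.step_electrode(
            self.params, self.state, inputs["I"], inputs["V_m"], self._dt
        )
        return {"V_rec": v_rec}


class AEC(Block):
    """Online active electrode compensation with an uploaded kernel."""

    in_ports = ("V_rec", "I")
    out_ports = ("V_hat",)

    def __init__(self, name: str, kernel: Kernel, enabled: bool = True):
        super().__init__(name)
        self.kernel = kernel
        self.enabled = bool(enabled)
        self.port_units = {"V_hat": "V"}

    def reset(self, dt, rng):
        if not math.isclose(dt, self.kernel.dt):
            raise ValueError("kernel dt does not match engine dt")
        self.state = AECState(electrode_kernel=self.kernel, enabled=self.enabled)

    def step(self, t, inputs):
        return {"V_hat": compensate_online(self.state, inputs["V_rec"], inputs["I"])}


class SpikeDetector(Block):
    """Streaming upward-crossing detector with refractory lockout."""

    in_ports = ("V",)
    out_ports = ("spike",)

    def __init__(self, name: str, threshold: float = -20e-3, refractory: float = 2e-3):
        super().__init__(name)
        self.threshold = float(threshold)
        self.refractory = float(refractory)

    def reset(self, dt, rng):
        self._dt = dt
        self._prev = -math.inf
        self._lock = 0.0

    def step(self, t, inputs):
        v = inputs["V"]
        spike = 0.0
        if self._lock > 0.0:
            self._lock -= self._dt
        elif self._prev < self.threshold <= v:
            spike = 1.0
            self._lock = self.refractory
        self._prev = v
        return {"spike": spike}


class RateMonitor(Block):
    """Spike-triggered sliding firing-rate estimate (sample-and-hold)."""

    in_ports = ("spike",)
    out_ports = ("r",)

    def __init__(self, name: str, tau_r: float = 1.0):
        super().__init__(name)
        self.tau_r = float(tau_r)
        self.port_units = {"r": "Hz"}

    def reset(self, dt, rng):
        self.state = controllers.RateEstimatorState(tau_r=self.tau_r)

    def step(self, t, inputs):
        if inputs["spike"] > 0.5:
            controllers.update_rate_estimate(self.state, t)
        return {"r": self.state.r}


class RateClampPID(Block):
    """Spike-triggered PID on the rate error, held between spikes."""

    in_ports = ("spike", "r")
    out_ports = ("I_ext",)

    def __init__(
        self,
        name: str,
        target: float,
        P: float = 0.0045,
        I: float = 0.0023,
        D: float = 0.0,
        output_scale: float = 1e-9,
        I_0: float = 0.0,
        output_limits=None,
    ):
        super().__init__(name)
        self.target = float(target)
        self.pid = controllers.PIDParams(
            P=P, I=I, D=D, output_scale=output_scale, bias=I_0,
            output_limits=output_limits,
        )
        self.port_units = {"I_ext": "A"}

    def reset(self, dt, rng):
        self.state = controllers.FiringRateClampState(held_output=self.pid.bias)

    def step(self, t, inputs):
        out = controllers.firing_rate_clamp_step(
            self.pid, self.state, self.target, inputs["r"], inputs["spike"] > 0.5
        )
        return {"I_ext": out}


class VoltageHold(Block):
    """Gated PI holding-current controller (current-clamp voltage hold)."""

    in_ports = ("V", "gate")
    out_ports = ("I_hold",)

    def __init__(
        self,
        name: str,
        V_target: float,
        P: float = 10.0,
        I: float = 100.0,
        output_scale: float = 1e-9,
    ):
        super().__init__(name)
        self.V_target = float(V_target)
        self.pid = controllers.PIDParams(P=P, I=I, D=0.0, output_scale=output_scale)
        self.port_units = {"I_hold": "A"}

    def reset(self, dt, rng):
        self._dt = dt
        self.state = controllers.VoltageHoldState()

    def step(self, t, inputs):
        out = controllers.voltage_hold_step(
            self.pid, self.state, self.V_target, inputs["V"], inputs["gate"] > 0.5, self._dt
        )
        return {"I_hold": out}


class UnitDelayDemo(Block):
    """Pass-through used by tests/examples of feedback semantics."""

    in_ports = ("u",)
    out_ports = ("y",)

    def __init__(self, name: str, gain: float = 1.0):
        super().__init__(name)
        self.gain = float(gain)

    def step(self, t, inputs):
        return {"y": self.gain * inputs["u"]}


BLOCK_REGISTRY = {
    "constant": ConstantSource,
    "waveform": WaveformSource,
    "sine": SineSource,
    "gain": Gain,
    "adder": Adder,
    "ou_conductance": OUConductance,
    "dynamic_clamp": DynamicClamp,
    "point_neuron": PointNeuron,
    "conductance_neuron": ConductanceNeuron,
    "tm_synapse": TMSynapse,
    "electrode": Electrode,
    "aec": AEC,
    "spike_detector": SpikeDetector,
    "rate_monitor": RateMonitor,
    "rate_clamp_pid": RateClampPID,
    "voltage_hold": VoltageHold,
    "delay_demo": UnitDelayDemo,
}
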