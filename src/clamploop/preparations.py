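"""In-silico stand-ins for the patched cell and the recording pipette.

These are the simulated "preparations" every protocol in the package runs
against: point-neuron models (leaky, quadratic and adaptive-exponential
integrate-and-fire), conductance-based spike-initiation models
(Hodgkin-Huxley squid parameters and the reduced Traub-Miles model), a
Tsodyks-Markram chemical synapse with short-term depression/facilitation,
and an RC model of the patch-pipette electrode.  They allow closed-loop
protocols to be exercised and debugged on a desk, with ground truth
available for every hidden variable.

All models are advanced by explicit Euler at the engine time step, except
the electrode whose linear ODE uses the exact exponential update (its time
constant can be far below the sampling interval, where Euler is unstable).
Units are SI throughout: V, A, S, F, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class PointNeuronParams:
    """Integrate-and-fire family parameters (SI units).

    ``model_kind`` is one of ``{"LIF", "QIF", "aEIF"}``.  The aEIF extras
    follow the adaptive exponential integrate-and-fire formulation
    (slope factor ``delta_T``, subthreshold adaptation ``a``, spike-triggered
    adaptation ``b``, adaptation time constant ``tau_w``); the QIF extra is
    the critical (unstable fixed point) voltage ``V_crit``.
    """

    model_kind: str = "LIF"
    C: float = 200e-12
    g_L: float = 10e-9
    E_L: float = -70e-3
    V_thresh: float = -50e-3
    V_reset: float = -58e-3
    t_ref: float = 2e-3
    # aEIF extras
    delta_T: float = 2e-3
    a: float = 0.0
    b: float = 0.0
    tau_w: float = 144e-3
    # QIF extra
    V_crit: float = -55e-3

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("C and g_L must be positive")
        if self.t_ref < 0 or self.tau_w <= 0:
            raise ValueError("t_ref must be >= 0 and tau_w > 0")
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must lie below V_thresh")
        if self.model_kind not in ("LIF", "QIF", "aEIF"):
            raise ValueError(f"unknown point-neuron kind {self.model_kind!r}")

    @property
    def cut_off(self) -> float:
        """Numerical spike-detection voltage.

        For the aEIF the upstroke diverges, so the spike is registered at
        ``V_thresh + 5*delta_T``; for LIF/QIF the stated threshold is used.
        """
        if self.model_kind == "aEIF":
            return self.V_thresh + 5.0 * self.delta_T
        return self.V_thresh


@dataclass
class ConductanceNeuronParams:
    """Hodgkin-Huxley-type parameters, absolute (area already folded in).

    Defaults are the classic squid-axon values scaled to a 20,000 um^2
    membrane patch (2e-4 cm^2), giving C = 200 pF and g_L = 60 nS.
    ``model_kind`` is ``"HH"`` or ``"TraubMilesReduced"``.
    """

    model_kind: str = "HH"
    C: float = 200e-12
    g_Na: float = 24e-6
    g_K: float = 7.2e-6
    g_L: float = 60e-9
    E_Na: float = 50e-3
    E_K: float = -77e-3
    E_L: float = -54.4e-3

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be non-negative")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("require E_K < E_L < E_Na")
        if self.model_kind not in ("HH", "TraubMilesReduced"):
            raise ValueError(f"unknown conductance-neuron kind {self.model_kind!r}")


def rtm_params() -> ConductanceNeuronParams:
    """Reduced Traub-Miles parameters on the same 2e-4 cm^2 patch."""
    return ConductanceNeuronParams(
        model_kind="TraubMilesReduced",
        C=200e-12,
        g_Na=20e-6,   # 100 mS/cm^2
        g_K=16e-6,    # 80 mS/cm^2
        g_L=20e-9,    # 0.1 mS/cm^2
        E_Na=50e-3,
        E_K=-100e-3,
        E_L=-67e-3,
    )


@dataclass
class TMSynapseParams:
    """Tsodyks-Markram short-term plasticity synapse.

    ``U``: utilisation increment per presynaptic spike; ``tau_rec``: resource
    recovery time; ``tau_facil``: facilitation decay (0 disables
    facilitation, pinning the utilisation at U); ``A``: absolute efficacy
    (peak PSC for a fully recovered, non-facilitated synapse is A*U), in S or
    A depending on use; ``tau_syn``: PSC decay time.
    """

    U: float = 0.5
    tau_rec: float = 0.5
    tau_facil: float = 0.0
    A: float = 1e-9
    tau_syn: float = 5e-3

    def __post_init__(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0 or self.tau_syn <= 0 or self.tau_facil < 0:
            raise ValueError("tau_rec, tau_syn must be > 0; tau_facil >= 0")


@dataclass
class ElectrodeParams:
    """Series-resistance / capacitance model of the patch pipette."""

    R_s: float = 10e6
    C_e: float = 1e-12

    def __post_init__(self) -> None:
        if self.R_s <= 0 or self.C_e < 0:
            raise ValueError("R_s must be > 0 and C_e >= 0")


@dataclass
class PreparationState:
    """Mutable state advanced per step.

    Only the fields a given model uses are meaningful; the rest stay at their
    defaults.  ``ref_left`` counts down the remaining refractory time,
    ``lockout_left`` the spike-detector lockout of conductance models.
    """

    V: float = -70e-3
    w: float = 0.0           # aEIF adaptation current (A)
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0
    u: float = 0.0           # TM utilisation
    x: float = 1.0           # TM resources
    psc: float = 0.0         # TM postsynaptic output (A or S)
    V_e: float = 0.0         # electrode voltage drop (V)
    last_spike_time: float = -math.inf
    ref_left: float = 0.0
    lockout_left: float = 0.0
    prev_V: float = field(default=-70e-3)

    def copy(self) -> "PreparationState":
        return replace(self)


def resting_potential(params: "ConductanceNeuronParams") -> float:
    """True resting potential: zero of the steady-state current balance
    with all gates at their voltage-dependent equilibria."""
    from scipy.optimize import brentq

    def steady_current(V: float) -> float:
        gates = {}
        for gate in ("m", "h", "n"):
            a, b = _rates(params.model_kind, gate, V)
            gates[gate] = a / (a + b)
        return (
            params.g_Na * gates["m"] ** 3 * gates["h"] * (params.E_Na - V)
            + params.g_K * gates["n"] ** 4 * (params.E_K - V)
            + params.g_L * (params.E_L - V)
        )

    # the steady-state current can have several zeros (rest, threshold,
    # depolarised); the resting potential is the most hyperpolarised one
    grid = np.arange(-90e-3, -35e-3, 0.5e-3)
    vals = [steady_current(v) for v in grid]
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0:
            return float(brentq(steady_current, grid[i], grid[i + 1]))
    raise ValueError("no resting potential found in [-90, -35] mV")


def init_state(params) -> PreparationState:
    """Resting state: point neurons start at V = E_L; conductance-based
    models at their emergent resting potential with gates at equilibrium."""
    if isinstance(params, ConductanceNeuronParams):
        v = resting_potential(params)
        st = PreparationState(V=v, prev_V=v)
        kind = params.model_kind
        for gate in ("m", "h", "n"):
            a, b = _rates(kind, gate, v)
            setattr(st, gate, a / (a + b))
        return st
    return PreparationState(V=params.E_L, prev_V=params.E_L)


# ---------------------------------------------------------------------------
# point-neuron models
# ---------------------------------------------------------------------------


def step_point_neuron(
    params: PointNeuronParams,
    state: PreparationState,
    I_in: float,
    dt: float,
) -> tuple[PreparationState, bool]:
    """One explicit-Euler step of an integrate-and-fire model.

    Returns the (mutated) state and a flag that is True exactly on the step
    where V crosses the numerical spike threshold, upon which V is reset,
    the aEIF adaptation increments by ``b`` and integration pauses for
    ``t_ref``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = state.V
    if state.ref_left > 0.0:
        state.ref_left -= dt
        if params.model_kind == "aEIF":
            state.w += dt * (params.a * (V - params.E_L) - state.w) / params.tau_w
        state.prev_V = V
        return state, False

    kind = params.model_kind
    if kind == "LIF":
        dV = (-params.g_L * (V - params.E_L) + I_in) / params.C
    elif kind == "QIF":
        k = params.g_L / (params.V_crit - params.E_L)
        dV = (k * (V - params.E_L) * (V - params.V_crit) + I_in) / params.C
    else:  # aEIF
        drive = math.exp(min((V - params.V_thresh) / params.delta_T, 30.0))
        dV = (
            -params.g_L * (V - params.E_L)
            + params.g_L * params.delta_T * drive
            - state.w
            + I_in
        ) / params.C
        state.w += dt * (params.a * (V - params.E_L) - state.w) / params.tau_w

    V_new = V + dt * dV
    spike = V_new >= params.cut_off
    if spike:
        V_new = params.V_reset
        state.ref_left = params.t_ref
        if kind == "aEIF":
            state.w += params.b
    if not math.isfinite(V_new):
        raise FloatingPointError("non-finite membrane potential in point neuron")
    state.prev_V = state.V
    state.V = V_new
    return state, spike


def lif_fi_rate(params: PointNeuronParams, I: float) -> float:
    """Closed-form stationary firing rate of the LIF under constant current.

    Returns 0 below rheobase ``g_L*(V_thresh - E_L)``.
    """
    tau = params.C / params.g_L
    v_inf = params.E_L + I / params.g_L
    if v_inf <= params.V_thresh:
        return 0.0
    T = params.t_ref + tau * math.log(
        (v_inf - params.V_reset) / (v_inf - params.V_thresh)
    )
    return 1.0 / T


# ---------------------------------------------------------------------------
# conductance-based models
# ---------------------------------------------------------------------------


def _vtrap(x: float, y: float) -> float:
    # x / (1 - exp(-x/y)), stable near x = 0
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / y / 2.0)
    return x / (1.0 - math.exp(-x / y))


def _rates(kind: str, gate: str, V: float) -> tuple[float, float]:
    """Voltage-dependent opening/closing rates in 1/s (V in volts)."""
    v = V * 1e3  # the canonical rate functions are written for mV and 1/ms
    if kind == "HH":
        if gate == "m":
            a = 0.1 * _vtrap(v + 40.0, 10.0)
            b = 4.0 * math.exp(-(v + 65.0) / 18.0)
        elif gate == "h":
            a = 0.07 * math.exp(-(v + 65.0) / 20.0)
            b = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
        else:
            a = 0.01 * _vtrap(v + 55.0, 10.0)
            b = 0.125 * math.exp(-(v + 65.0) / 80.0)
    else:  # TraubMilesReduced
        if gate == "m":
            a = 0.32 * _vtrap(v + 54.0, 4.0)
            b = 0.28 * _vtrap(-(v + 27.0), 5.0)
        elif gate == "h":
            a = 0.128 * math.exp(-(v + 50.0) / 18.0)
            b = 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))
        else:
            a = 0.032 * _vtrap(v + 52.0, 5.0)
            b = 0.5 * math.exp(-(v + 57.0) / 40.0)
    return a * 1e3, b * 1e3


#: Spike-detection threshold and lockout for conductance models.
SPIKE_CROSSING_V = 0.0
SPIKE_LOCKOUT = 2e-3


def step_conductance_neuron(
    params: ConductanceNeuronParams,
    state: PreparationState,
    I_in: float,
    dt: float,
) -> tuple[PreparationState, bool]:
    """One Euler step of a Hodgkin-Huxley-type model.

    Spikes are flagged on upward crossings of 0 mV with a 2 ms lockout.
    A gating variable leaving [-0.01, 1.01] aborts: at the recommended
    dt <= 25 us this signals numerical instability, not biology.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = state.V
    kind = params.model_kind
    for gate in ("m", "h", "n"):
        a, b = _rates(kind, gate, V)
        val = getattr(state, gate)
        val += dt * (a * (1.0 - val) - b * val)
        if not (-0.01 <= val <= 1.01):
            raise FloatingPointError(
                f"gating variable {gate} = {val:.4f} left [0, 1]; reduce dt"
            )
        setattr(state, gate, val)
    I_Na = params.g_Na * state.m**3 * state.h * (params.E_Na - V)
    I_K = params.g_K * state.n**4 * (params.E_K - V)
    I_L = params.g_L * (params.E_L - V)
    V_new = V + dt * (I_Na + I_K + I_L + I_in) / params.C
    if not math.isfinite(V_new):
        raise FloatingPointError("non-finite membrane potential in conductance neuron")

    spike = False
    if state.lockout_left > 0.0:
        state.lockout_left -= dt
    elif state.V < SPIKE_CROSSING_V <= V_new:
        spike = True
        state.lockout_left = SPIKE_LOCKOUT
    state.prev_V = state.V
    state.V = V_new
    return state, spike


# ---------------------------------------------------------------------------
# Tsodyks-Markram synapse
# ---------------------------------------------------------------------------


def step_tm_synapse(
    params: TMSynapseParams,
    state: PreparationState,
    presyn_spike: bool,
    dt: float,
) -> tuple[PreparationState, float]:
    """One step of the depressing/facilitating synapse.

    Between spikes the resources ``x`` recover toward 1 with ``tau_rec``,
    the utilisation ``u`` decays toward 0 with ``tau_facil`` (or stays
    pinned at U when facilitation is disabled) and the postsynaptic output
    decays with ``tau_syn``.  On a presynaptic spike a fraction ``u*x`` of
    the resources is released and the output increments by ``A*u*x``.

    The inter-spike dynamics are linear, so the decays use the exact
    exponential update (dt-step-size independent between events).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.x = 1.0 - (1.0 - state.x) * math.exp(-dt / params.tau_rec)
    if params.tau_facil > 0.0:
        state.u *= math.exp(-dt / params.tau_facil)
    else:
        state.u = params.U
    state.psc *= math.exp(-dt / params.tau_syn)
    if presyn_spike:
        if params.tau_facil > 0.0:
            state.u += params.U * (1.0 - state.u)
        release = state.u * state.x
        state.x -= release
        state.psc += params.A * release
    state.x = min(max(state.x, 0.0), 1.0)
    state.u = min(max(state.u, 0.0), 1.0)
    return state, state.psc


def tm_depression_fixed_point(params: TMSynapseParams, isi: float) -> float:
    """Steady-state PSC amplitude for a regular train (no facilitation).

    Closed form of the depression map: with e = exp(-isi/tau_rec) the
    pre-spike resource fixed point is x* = (1 - e) / (1 - (1 - U) e) and the
    amplitude is A * U * x*.
    """
    e = math.exp(-isi / params.tau_rec)
    x_star = (1.0 - e) / (1.0 - (1.0 - params.U) * e)
    return params.A * params.U * x_star


# ---------------------------------------------------------------------------
# electrode
# ---------------------------------------------------------------------------


def step_electrode(
    params: ElectrodeParams,
    state: PreparationState,
    I_pipette: float,
    V_membrane: float,
    dt: float,
) -> tuple[PreparationState, float]:
    """Advance the electrode voltage drop and return the recorded potential.

    The recorded potential is the membrane potential plus the voltage across
    the electrode RC circuit driven by the pipette current (a pure resistor
    when C_e = 0).  The linear ODE is integrated exactly for a
    piecewise-constant current, so any dt is admissible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.C_e == 0.0:
        state.V_e = params.R_s * I_pipette
    else:
        lam = math.exp(-dt / (params.R_s * params.C_e))
        state.V_e = lam * state.V_e + params.R_s * (1.0 - lam) * I_pipette
    return state, V_membrane + state.V_e


# ---------------------------------------------------------------------------
# named preparations
# ---------------------------------------------------------------------------


def default_l5_params() -> PointNeuronParams:
    """Calibrated L5-pyramidal-like aEIF preparation.

    Resting input conductance 10 nS, rest -70 mV, threshold -50 mV, membrane
    time constant 20 ms, modest adaptation.  With this cell the conventional
    "2% / 6% of resting input conductance" rule gives unitary background
    conductances g_e = 0.2 nS and g_i = 0.6 nS.
    """
    return PointNeuronParams(
        model_kind="aEIF",
        C=200e-12,
        g_L=10e-9,
        E_L=-70e-3,
        V_thresh=-50e-3,
        V_reset=-58e-3,
        t_ref=2e-3,
        delta_T=2e-3,
        a=2e-9,
        b=40e-12,
        tau_w=144e-3,
    )


def passive_params() -> PointNeuronParams:
    """Passive RC membrane: the LIF with an unreachably high threshold."""
    return PointNeuronParams(
        model_kind="LIF",
        C=200e-12,
        g_L=10e-9,
        E_L=-70e-3,
        V_thresh=1.0,
        V_reset=-70e-3,
        t_ref=0.0,
    )


PREPARATIONS: dict = {
    "l5_aeif": default_l5_params,
    "lif": PointNeuronParams,
    "qif": lambda: PointNeuronParams(model_kind="QIF", V_thresh=-40e-3),
    "passive": passive_params,
    "hh": ConductanceNeuronParams,
    "rtm": rtm_params,
}


def make_preparation(name: str, **overrides):
    """Look up a named preparation and apply parameter overrides (SI)."""
    if name not in PREPARATIONS:
        raise KeyError(f"unknown preparation {name!r}; known: {sorted(PREPARATIONS)}")
    params = PREPARATIONS[name]()
    if overrides:
        params = replace(params, **overrides)
    return params
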