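"""Open-loop signal synthesis.

Covers the point-conductance description of background synaptic activity
(Ornstein-Uhlenbeck conductances under the diffusion approximation),
sinusoidal modulation of the virtual presynaptic rates, the per-step
dynamic-clamp law converting conductances into injected current, the
excitatory/inhibitory balance solver, and arbitrary stimulus waveforms
(pulses, ramps, sinusoids, noise) with concatenation and algebraic
combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import Trace


# ---------------------------------------------------------------------------
# point-conductance background
# ---------------------------------------------------------------------------


@dataclass
class SynapticChannelParams:
    """One virtual presynaptic population: unitary conductance ``g`` (S),
    synaptic correlation time ``tau`` (s), activation rate ``R`` (Hz) and
    reversal potential ``E`` (V)."""

    g: float
    tau: float
    R: float
    E: float

    def __post_init__(self) -> None:
        if self.g < 0 or self.tau < 0 or self.R < 0:
            raise ValueError("g, tau and R must be non-negative")


#: Conventional excitatory / inhibitory channels for the default L5-like
#: preparation: unitary conductances at 2% and 6% of the 10 nS resting input
#: conductance, reversals 0 mV and -80 mV, correlation times 5 ms and 10 ms.
def default_channels(R_e: float = 7000.0, R_i: float = 2149.0):
    exc = SynapticChannelParams(g=0.2e-9, tau=5e-3, R=R_e, E=0.0)
    inh = SynapticChannelParams(g=0.6e-9, tau=10e-3, R=R_i, E=-80e-3)
    return exc, inh


def diffusion_moments(g: float, tau: float, R: float) -> tuple[float, float]:
    """Stationary mean and standard deviation of the diffusion-approximated
    synaptic conductance for a Poisson population.

    ``G_bar = g * tau * R`` and ``G_S = sqrt(g**2 * tau * R / 2)``.
    """
    if g < 0 or tau < 0 or R < 0:
        raise ValueError("g, tau and R must be non-negative")
    G_bar = g * tau * R
    G_S = math.sqrt(0.5 * g * g * tau * R)
    return G_bar, G_S


@dataclass
class OUProcessParams:
    """Ornstein-Uhlenbeck conductance parameters.

    The diffusion coefficient is tied to the stationary moments on
    construction: ``D = G_S**2 / tau``.
    """

    G_bar: float
    G_S: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.G_S < 0:
            raise ValueError("G_S must be non-negative")

    @property
    def D(self) -> float:
        return self.G_S**2 / self.tau

    @classmethod
    def from_channel(cls, ch: SynapticChannelParams) -> "OUProcessParams":
        G_bar, G_S = diffusion_moments(ch.g, ch.tau, ch.R)
        return cls(G_bar=G_bar, G_S=G_S, tau=ch.tau)


def ou_step(params: OUProcessParams, G: float, dt: float, noise_draw: float) -> float:
    """One Euler-Maruyama step of the OU conductance SDE.

    ``G' = G + dt*(G_bar - G)/tau + sqrt(2*D*dt)*xi`` with ``xi`` a standard
    normal draw.  Negative excursions are passed through here; clipping to
    zero happens only at the injection point (dynamic-clamp convention).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (
        G
        + dt * (params.G_bar - G) / params.tau
        + math.sqrt(2.0 * params.D * dt) * noise_draw
    )


@dataclass
class RateModulationParams:
    """Sinusoidal modulation of a presynaptic rate: offset ``R0`` (Hz),
    peak amplitude ``R1`` (Hz) and angular frequency ``omega`` (rad/s).
    An optional ``phase`` (rad) defaults to 0."""

    R0: float
    R1: float
    omega: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.R0 >= self.R1 >= 0):
            raise ValueError("need R0 >= R1 >= 0 so the rate never goes negative")


def modulated_rate(params: RateModulationParams, t: float) -> float:
    """Instantaneous rate ``R0 + R1*sin(omega*t + phase)``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return params.R0 + params.R1 * math.sin(params.omega * t + params.phase)


def conductance_to_current(
    G_e: float, G_i: float, V: float, E_e: float = 0.0, E_i: float = -80e-3
) -> float:
    """The per-step dynamic-clamp law.

    ``I_syn = G_e*(E_e - V) + G_i*(E_i - V)``, recomputed every sample from
    the instantaneous (compensated) membrane potential.  Conductances are
    clipped to zero here — the injection point — preserving the OU
    statistics upstream.
    """
    G_e = max(G_e, 0.0)
    G_i = max(G_i, 0.0)
    return G_e * (E_e - V) + G_i * (E_i - V)


def balance_inhibitory_rate(
    R_e: float,
    exc: SynapticChannelParams,
    inh: SynapticChannelParams,
    V_b: float,
) -> float:
    """Inhibitory rate balancing the mean injected current at ``V_b``.

    Solves ``0 = <G_e>(E_e - V_b) + <G_i>(E_i - V_b)`` with the diffusion
    means ``<G_x> = g_x * tau_x * R_x``, i.e.::

        R_i = g_e*tau_e*R_e*(E_e - V_b) / (g_i*tau_i*(V_b - E_i))

    ``V_b`` must lie strictly between the reversals, otherwise no
    non-negative balancing rate exists.
    """
    if not (inh.E < V_b < exc.E):
        raise ValueError(
            f"balance potential {V_b} must lie strictly between E_i={inh.E} "
            f"and E_e={exc.E}"
        )
    if R_e < 0:
        raise ValueError("R_e must be non-negative")
    return (exc.g * exc.tau * R_e * (exc.E - V_b)) / (inh.g * inh.tau * (V_b - inh.E))


# ---------------------------------------------------------------------------
# arbitrary waveforms
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One waveform segment; ``kind`` in {constant, pulse, ramp, sinusoid,
    ou_noise} with keyword parameters as used by :func:`compile_waveform`."""

    kind: str
    duration: float
    params: dict

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind not in ("constant", "pulse", "ramp", "sinusoid", "ou_noise"):
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass
class WaveformSpec:
    """An ordered concatenation of segments with a unit tag.

    ``scale`` multiplies the compiled trace; specs of equal dt and length can
    be combined sample-wise with :func:`sum_waveforms`.
    """

    segments: list
    unit: str = "A"
    scale: float = 1.0

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)


def _compile_segment(seg: Segment, dt: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(seg.duration / dt))
    t = dt * np.arange(n)
    p = seg.params
    if seg.kind == "constant":
        return np.full(n, float(p["value"]))
    if seg.kind == "pulse":
        out = np.full(n, float(p.get("baseline", 0.0)))
        on = (t >= p.get("onset", 0.0)) & (t < p.get("onset", 0.0) + p["width"])
        out[on] = p["amplitude"]
        return out
    if seg.kind == "ramp":
        v0, v1 = float(p["start"]), float(p["stop"])
        if n == 1:
            return np.array([v0])
        return v0 + (v1 - v0) * t / (dt * (n - 1))
    if seg.kind == "sinusoid":
        return p.get("offset", 0.0) + p["amplitude"] * np.sin(
            2.0 * math.pi * p["frequency"] * t + p.get("phase", 0.0)
        )
    # ou_noise: mean, sd, tau
    ou = OUProcessParams(G_bar=p["mean"], G_S=p["sd"], tau=p["tau"])
    out = np.empty(n)
    g = p.get("start", p["mean"])
    draws = rng.standard_normal(n)
    for i in range(n):
        g = ou_step(ou, g, dt, draws[i])
        out[i] = g
    return out


def compile_waveform(spec: WaveformSpec, dt: float, seed: int = 0) -> Trace:
    """Render a :class:`WaveformSpec` into a :class:`Trace`.

    Deterministic for a given ``(spec, dt, seed)``; segment lengths
    concatenate exactly (each segment contributes ``round(duration/dt)``
    samples).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    parts = [_compile_segment(s, dt, rng) for s in spec.segments]
    values = np.concatenate(parts) if parts else np.empty(0)
    return Trace(dt=dt, values=spec.scale * values, unit=spec.unit)


def sum_waveforms(*traces: Trace) -> Trace:
    """Sample-wise sum of aligned traces (same dt, length and unit)."""
    if not traces:
        raise ValueError("need at least one trace")
    dt0, n0, u0 = traces[0].dt, len(traces[0]), traces[0].unit
    for tr in traces[1:]:
        if not math.isclose(tr.dt, dt0) or len(tr) != n0 or tr.unit != u0:
            raise ValueError("traces must share dt, length and unit to combine")
    total = np.sum([tr.values for tr in traces], axis=0)
    return Trace(dt=dt0, values=total, unit=u0, t0=traces[0].t0)


def read_waveform_file(path) -> Trace:
    """Read a two-column (time, value) waveform file at fixed dt.

    Header comment lines ``# unit=...`` are honoured; the sampling interval
    is taken from the first two time stamps and checked for uniformity.
    """
    unit = "1"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "unit=" in line:
                unit = line.split("unit=")[1].strip()
            if not line.startswith("#"):
                break
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("waveform file must have two columns and >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        raise ValueError("waveform file is not uniformly sampled")
    return Trace(dt=float(dt), values=v, unit=unit, t0=float(t[0]))


def write_waveform_file(path, trace: Trace) -> None:
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, header=f"unit={trace.unit}", comments="# ")
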