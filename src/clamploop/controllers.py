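"""Closed-loop regulation blocks.

Spike detection, spike-triggered firing-rate estimation, the
sample-and-hold PID firing-rate clamp, the gated PI membrane-potential
hold, the sliding response-probability estimate with PI stimulus-intensity
control (response clamp), and evoked-PSP amplitude measurement for the
EPSP-size clamp.

Two discretisation conventions coexist deliberately.  Event-triggered
controllers (firing-rate clamp, stimulus-intensity control) accumulate
error per event with *no* dt factor — each spike or stimulus is one
controller iteration, and outputs hold between events.  The voltage hold
runs at the engine step and therefore uses the continuous-time convention,
integrating the error over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trace import Trace, TriggeredSegment


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------


@dataclass
class SpikeDetectorParams:
    """Upward threshold-crossing detector with refractory lockout and an
    optional (start, end) detection window in seconds."""

    threshold: float = -20e-3
    refractory: float = 2e-3
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


def detect_spikes(V: Trace, params: SpikeDetectorParams) -> np.ndarray:
    """Times of upward threshold crossings, separated by >= refractory.

    Restricted to ``params.window`` when set.  The first sample can never be
    a crossing (no predecessor to cross from).
    """
    if len(V) == 0:
        raise ValueError("empty trace")
    v = V.values
    above = v >= params.threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = V.t0 + crossings * V.dt
    if params.window is not None:
        lo, hi = params.window
        times = times[(times >= lo) & (times <= hi)]
    if params.refractory > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= params.refractory:
                kept.append(t)
        times = np.array(kept)
    return np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# spike-triggered rate estimation
# ---------------------------------------------------------------------------


@dataclass
class RateEstimatorState:
    """Sliding firing-rate estimate updated at each action potential.

    On a spike at time ``t`` with inter-spike interval ``isi``::

        r <- r*exp(-isi/tau_r) + (1/isi)*(1 - exp(-isi/tau_r))

    a weighted average between the rate history and the inverse of the last
    interval; there are no inter-spike updates (sample-and-hold).
    """

    tau_r: float = 1.0
    r: float = 0.0
    last_spike_time: float = -math.inf

    def __post_init__(self) -> None:
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.r < 0:
            raise ValueError("rate estimate must be non-negative")


def update_rate_estimate(state: RateEstimatorState, spike_time: float) -> RateEstimatorState:
    """Event-triggered update; ``spike_time`` must exceed the last one."""
    if spike_time <= state.last_spike_time:
        raise ValueError("spike times must be strictly increasing")
    if math.isinf(state.last_spike_time):
        # first observed spike: no interval yet, keep the prior estimate
        state.last_spike_time = spike_time
        return state
    isi = spike_time - state.last_spike_time
    w = math.exp(-isi / state.tau_r)
    state.r = state.r * w + (1.0 / isi) * (1.0 - w)
    state.last_spike_time = spike_time
    return state


# ---------------------------------------------------------------------------
# PID firing-rate clamp (spike-triggered, sample-and-hold)
# ---------------------------------------------------------------------------


@dataclass
class PIDParams:
    """PID gains.  For the firing-rate clamp the error is in Hz and the
    output in nA (``output_scale`` converts to amperes); accumulation is per
    event with no dt factor.  ``output_limits`` clamps the emitted value."""

    P: float = 0.0045
    I: float = 0.0023
    D: float = 0.0
    output_scale: float = 1e-9
    bias: float = 0.0
    output_limits: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.output_limits is not None and self.output_limits[0] > self.output_limits[1]:
            raise ValueError("output_limits must be ordered")


@dataclass
class FiringRateClampState:
    """Accumulators of the spike-triggered PID: per-event integral ``EI``,
    previous error, and the held output (A)."""

    EI: float = 0.0
    prev_error: float = 0.0
    have_prev: bool = False
    held_output: float = 0.0
    saturated: int = 0


def firing_rate_clamp_step(
    pid: PIDParams,
    state: FiringRateClampState,
    target_rate: float,
    estimate: float,
    event: bool,
) -> float:
    """One engine step of the firing-rate clamp.

    The output updates only on spike events (sample-and-hold): discrete PID
    on the error ``target - estimate`` with per-event accumulation and the
    derivative on the error difference between events, around the constant
    offset ``pid.bias`` (the experimenter's initial external current; the
    held output equals the bias until the first spike).  Saturation against
    ``output_limits`` is counted, not fatal.
    """
    if not event:
        return state.held_output
    e = target_rate - estimate
    state.EI += e
    de = (e - state.prev_error) if state.have_prev else 0.0
    state.prev_error = e
    state.have_prev = True
    out = pid.bias + pid.output_scale * (pid.P * e + pid.I * state.EI + pid.D * de)
    if pid.output_limits is not None:
        lo, hi = pid.output_limits
        clipped = min(max(out, lo), hi)
        if clipped != out:
            state.saturated += 1
        out = clipped
    state.held_output = out
    return out


# ---------------------------------------------------------------------------
# gated PI voltage hold (current-clamp)
# ---------------------------------------------------------------------------


@dataclass
class VoltageHoldState:
    """Continuous-time PI accumulator for the membrane-potential hold."""

    EI: float = 0.0  # integral of error (V*s)
    held_output: float = 0.0  # A


def voltage_hold_step(
    pid: PIDParams,
    state: VoltageHoldState,
    V_target: float,
    V_measured: float,
    gate_open: bool,
    dt: float,
) -> float:
    """One engine step of the PI holding-current controller.

    While the gate is open the holding current is
    ``output_scale*(P*e + I*integral(e dt))`` with ``e = V_target - V``.
    While gated closed — e.g. around an extracellular stimulus, to avoid
    interfering with the evoked response — the output freezes at its last
    value and the integral does not advance.
    """
    if not gate_open:
        return state.held_output
    e = V_target - V_measured
    state.EI += e * dt
    out = pid.output_scale * (pid.P * e + pid.I * state.EI)
    if pid.output_limits is not None:
        out = min(max(out, pid.output_limits[0]), pid.output_limits[1])
    state.held_output = out
    return out


# ---------------------------------------------------------------------------
# response-probability estimate and stimulus-intensity control
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityState:
    """Sliding estimate of the evoked response probability.

    Per stimulus ``n``::

        p_n = p_{n-1} * exp(-ISI/tau) + F * (1 - exp(-ISI/tau))

    with ``F = 1`` if the stimulus evoked a spike in the recording window,
    else 0.  A convex combination, so p stays in [0, 1].  The same update
    with ``F`` replaced by the last evoked PSP amplitude gives the sliding
    amplitude average of the EPSP-size clamp (then ``p`` is in volts and
    the [0, 1] bound does not apply).
    """

    tau: float = 600.0
    ISI: float = 4.0
    p: float = 0.0
    bounded: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.ISI <= 0:
            raise ValueError("tau and ISI must be positive")
        if self.bounded and not (0.0 <= self.p <= 1.0):
            raise ValueError("p must start in [0, 1]")

    @property
    def decay(self) -> float:
        return math.exp(-self.ISI / self.tau)


def update_response_probability(state: ProbabilityState, responded) -> ProbabilityState:
    """Apply the sliding-estimate update with F = 1/0 (or a float value)."""
    F = float(responded)
    w = state.decay
    state.p = state.p * w + F * (1.0 - w)
    if state.bounded:
        state.p = min(max(state.p, 0.0), 1.0)
    return state


@dataclass
class StimulusControllerState:
    """PI control of the extracellular stimulus intensity.

    Per stimulus: ``EP = target - measured``, ``EI += EP`` and the next
    intensity is ``S = S_1 + G*(P_pid*EP + I_pid*EI)`` (dimensionless
    device-unit accumulation, no dt factor).  ``bounds`` clips the emitted
    intensity against the stimulator range, counting the event.
    """

    S_1: float
    G: float = 700.0
    P_pid: float = 1.0
    I_pid: float = 0.3
    target: float = 0.5
    EI: float = 0.0
    bounds: tuple[float, float] | None = None
    clipped: int = 0


def next_stimulus_intensity(state: StimulusControllerState, measured: float) -> float:
    """Compute the intensity of the next stimulus from the latest estimate."""
    EP = state.target - measured
    state.EI += EP
    S = state.S_1 + state.G * (state.P_pid * EP + state.I_pid * state.EI)
    if state.bounds is not None:
        lo, hi = state.bounds
        S_clipped = min(max(S, lo), hi)
        if S_clipped != S:
            state.clipped += 1
        S = S_clipped
    return S


@dataclass
class BiphasicPulseSpec:
    """Charge-balanced biphasic current pulse (equal-magnitude phases),
    200 us per phase by default, positive phase first."""

    amplitude: float = 0.0
    phase_width: float = 200e-6
    positive_first: bool = True

    def __post_init__(self) -> None:
        if self.phase_width <= 0:
            raise ValueError("phase_width must be positive")

    def waveform(self, dt: float) -> np.ndarray:
        n = max(int(round(self.phase_width / dt)), 1)
        sign = 1.0 if self.positive_first else -1.0
        return np.concatenate(
            [np.full(n, sign * self.amplitude), np.full(n, -sign * self.amplitude)]
        )


# ---------------------------------------------------------------------------
# PSP amplitude measurement
# ---------------------------------------------------------------------------


def measure_psp_amplitude(
    segment: TriggeredSegment,
    baseline_window: float,
    search_window: float,
    polarity: str = "positive",
    channel: str = "V",
) -> float:
    """Evoked-PSP peak amplitude from a triggered segment.

    Amplitude = extremum of the voltage within ``search_window`` after the
    trigger minus the mean over the ``baseline_window`` preceding it,
    signed by ``polarity`` ("positive" returns max-baseline, "negative"
    baseline-min).
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if channel not in segment.traces:
        raise ValueError(f"segment has no channel {channel!r}")
    tr = segment.traces[channel]
    if baseline_window > segment.pre_window + 1e-12:
        raise ValueError("baseline window exceeds the segment's pre-trigger span")
    if search_window > segment.post_window + 1e-12:
        raise ValueError("search window exceeds the segment's post-trigger span")
    i_trig = int(round(segment.pre_window / tr.dt))
    n_base = max(int(round(baseline_window / tr.dt)), 1)
    n_search = max(int(round(search_window / tr.dt)), 1)
    base = float(tr.values[max(i_trig - n_base, 0) : i_trig].mean()) if i_trig else float(
        tr.values[0]
    )
    seg = tr.values[i_trig : i_trig + n_search + 1]
    if polarity == "positive":
        return float(seg.max() - base)
    return float(base - seg.min())
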