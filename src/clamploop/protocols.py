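"""Executable demonstrator protocols against simulated preparations.

Each protocol assembles the library's blocks into a runnable experiment:

``arbitrary_stream_and_record``
    Open-loop current injection with voltage recording.
``conductance_clamp``
    Dynamic clamp with stationary OU background conductances
    (the high-conductance-state recreation).
``sine_modulated_background``
    Conductance clamp with sinusoidally modulated presynaptic rates, with
    or without the synaptic low-pass filtering of the modulation, plus the
    cycle-histogram transfer analysis.
``firing_rate_clamp``
    Spike-triggered PID control of an external current holding the mean
    firing rate at a setpoint.
``voltage_hold``
    Gated PI holding-current control of the membrane potential.
``response_probability_clamp``
    PI control of extracellular stimulus intensity holding the evoked
    spike probability at a target, on a preparation whose
    stimulus-response threshold drifts slowly.
``epsp_size_clamp``
    The same feedback law holding the evoked PSP peak amplitude at a
    target, on a depressing synapse with drifting efficacy.

The extracellular protocols run at stimulus-event resolution: threshold or
efficacy drift is advanced per stimulus with the exact OU transition, each
stimulus produces a short triggered recording window, and the sliding
estimate / PI intensity updates are applied per stimulus exactly as in the
online implementation.  Recruitment-curve and drift parameters are
declared fixture parameters of the simulated preparation, not biological
claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, blocks, controllers, io, preparations, stimgen
from .aec import Kernel, estimate_full_kernel, split_electrode_kernel, generate_probe_current
from .engine import BlockGraph, LogStore, Wire, run_fixed_step, segment_logger
from .trace import Trace, TriggeredSegment

#: Balance potential used to compute inhibitory rates: 1-2 mV below the
#: -50 mV threshold of the default preparation (back-solved so that the
#: canonical 1x condition R_e = 7000 Hz balances at R_i = 2149 Hz).
V_BALANCE = -51.85e-3

#: Background scale conditions: multiples of the 1x excitatory rate 7000 Hz.
BACKGROUND_SCALES = {"0x": 0.0, "1x": 7000.0, "2x": 14000.0, "3x": 21000.0}


@dataclass
class ProtocolConfig:
    """Everything needed to launch a protocol run."""

    protocol: str
    duration: float = 10.0
    dt: float = 5e-5
    seed: int = 0
    preparation: str = "l5_aeif"
    overrides: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


@dataclass
class ProtocolResult:
    """Run artifacts: continuous logs, event table, derived summary."""

    config: ProtocolConfig
    logs: LogStore | None = None
    events: pd.DataFrame | None = None
    segments: list[TriggeredSegment] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def save(self) -> None:
        if self.config.out_dir is None:
            return
        out = Path(self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.logs is not None:
            io.write_log_store(out / "log.tsv", self.logs)
        if self.events is not None:
            io.write_events(out / "events.tsv", self.events)
        if self.segments:
            io.write_segments(out / "segments", self.segments)
        if self.summary:
            with open(out / "summary.tsv", "w") as fh:
                for k, v in self.summary.items():
                    fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# graph builders for the continuous protocols
# ---------------------------------------------------------------------------


def _neuron_block(cfg: ProtocolConfig, name: str = "neuron"):
    params = preparations.make_preparation(cfg.preparation, **cfg.overrides)
    if isinstance(params, preparations.ConductanceNeuronParams):
        return blocks.ConductanceNeuron(name, params=params)
    return blocks.PointNeuron(name, params=params)


def background_rates(scale: str | float, R_i: float | None = None) -> tuple[float, float]:
    """Excitatory/inhibitory rates for a background condition.

    ``scale`` is one of the named conditions ("0x".."3x") or an explicit
    excitatory rate in Hz; the inhibitory rate balances the mean injected
    current at :data:`V_BALANCE` unless given explicitly.
    """
    R_e = BACKGROUND_SCALES[scale] if isinstance(scale, str) else float(scale)
    if R_i is None:
        if R_e == 0.0:
            R_i = 0.0
        else:
            exc, inh = stimgen.default_channels()
            R_i = stimgen.balance_inhibitory_rate(R_e, exc, inh, V_BALANCE)
    return R_e, R_i


def _background_blocks(R_e: float, R_i: float, mod: dict | None = None):
    """OU conductance blocks for both channels (modulation optional)."""
    exc, inh = stimgen.default_channels()
    mod = mod or {}
    kw_e = kw_i = {}
    if mod:
        omega = 2.0 * math.pi * mod["frequency"]
        frac = mod.get("fraction", 0.1)
        filt = mod.get("filter_modulation", True)
        which = mod.get("channels", "e")
        if which in ("e", "both"):
            kw_e = dict(R1=frac * R_e, omega=omega, filter_modulation=filt)
        if which in ("i", "both"):
            kw_i = dict(R1=frac * R_i, omega=omega, filter_modulation=filt)
    ou_e = blocks.OUConductance("ou_e", g=exc.g, tau=exc.tau, R=R_e, **kw_e)
    ou_i = blocks.OUConductance("ou_i", g=inh.g, tau=inh.tau, R=R_i, **kw_i)
    return ou_e, ou_i, exc, inh


def build_conductance_clamp_graph(
    cfg: ProtocolConfig,
    R_e: float,
    R_i: float,
    I_ext: float = 0.0,
    mod: dict | None = None,
    rate_clamp: dict | None = None,
    electrode: preparations.ElectrodeParams | None = None,
    kernel: Kernel | None = None,
) -> BlockGraph:
    """Wire the dynamic-clamp loop, optionally through a simulated electrode
    with AEC and/or with the spike-triggered firing-rate PID."""
    neuron = _neuron_block(cfg)
    ou_e, ou_i, exc, inh = _background_blocks(R_e, R_i, mod)
    clamp = blocks.DynamicClamp("clamp", E_e=exc.E, E_i=inh.E)
    isum = blocks.Adder("isum")
    blist = [ou_e, ou_i, clamp, isum, neuron]
    v_init = preparations.make_preparation(cfg.preparation, **cfg.overrides).E_L
    wires = [
        Wire("ou_e.G", "clamp.G_e"),
        Wire("ou_i.G", "clamp.G_i"),
        Wire("clamp.I", "isum.a"),
        Wire("isum.y", "neuron.I"),
    ]
    constants = {"isum.c": 0.0}
    log = ["neuron.V", "neuron.spike", "clamp.I", "ou_e.G", "ou_i.G"]

    if electrode is not None:
        el = blocks.Electrode("electrode", params=electrode)
        blist.append(el)
        wires += [Wire("isum.y", "electrode.I"), Wire("neuron.V", "electrode.V_m")]
        if kernel is not None:
            aec_blk = blocks.AEC("aec", kernel=kernel, enabled=True)
            blist.append(aec_blk)
            wires += [
                Wire("electrode.V_rec", "aec.V_rec"),
                Wire("isum.y", "aec.I"),
                Wire("aec.V_hat", "clamp.V", feedback=True, init=v_init),
            ]
            log += ["electrode.V_rec", "aec.V_hat"]
        else:
            wires.append(Wire("electrode.V_rec", "clamp.V", feedback=True, init=v_init))
            log += ["electrode.V_rec"]
    else:
        wires.append(Wire("neuron.V", "clamp.V", feedback=True, init=v_init))

    if rate_clamp is not None:
        mon = blocks.RateMonitor("monitor", tau_r=rate_clamp.get("tau_r", 1.0))
        pid = blocks.RateClampPID(
            "pid",
            target=rate_clamp["target"],
            P=rate_clamp.get("P", 0.0045),
            I=rate_clamp.get("I", 0.0023),
            D=rate_clamp.get("D", 0.0),
            I_0=rate_clamp.get("I_0", 0.2e-9),
        )
        blist += [mon, pid]
        wires += [
            Wire("neuron.spike", "monitor.spike"),
            Wire("neuron.spike", "pid.spike"),
            Wire("monitor.r", "pid.r"),
            Wire("pid.I_ext", "isum.b", feedback=True, init=pid.pid.bias),
        ]
        log += ["monitor.r", "pid.I_ext"]
        # external-current input port is taken by the controller
        wires.append(Wire("iext.y", "isum.c"))
        del constants["isum.c"]
        blist.append(blocks.ConstantSource("iext", value=I_ext, unit="A"))
    else:
        constants["isum.b"] = float(I_ext)

    wires = [w for w in wires if w.src != "iext.y" or any(b.name == "iext" for b in blist)]
    return BlockGraph(blist, wires, constants=constants, log=log)


# ---------------------------------------------------------------------------
# continuous protocols
# ---------------------------------------------------------------------------


def _arbitrary_stream_and_record(cfg: ProtocolConfig) -> ProtocolResult:
    wf = cfg.params.get("waveform")
    if wf is None:
        wf = Trace(dt=cfg.dt, values=np.zeros(int(round(cfg.duration / cfg.dt))), unit="A")
    elif isinstance(wf, dict):
        # config-file form: {unit: A, scale: 1.0, segments: [{kind, duration, ...}]}
        spec = stimgen.WaveformSpec(
            segments=[
                stimgen.Segment(
                    kind=s["kind"],
                    duration=float(s["duration"]),
                    params={k: v for k, v in s.items() if k not in ("kind", "duration")},
                )
                for s in wf.get("segments", [])
            ],
            unit=wf.get("unit", "A"),
            scale=float(wf.get("scale", 1.0)),
        )
        wf = stimgen.compile_waveform(spec, cfg.dt, seed=cfg.seed)
    elif isinstance(wf, stimgen.WaveformSpec):
        wf = stimgen.compile_waveform(wf, cfg.dt, seed=cfg.seed)
    src = blocks.WaveformSource("stim", trace=wf)
    neuron = _neuron_block(cfg)
    graph = BlockGraph(
        [src, neuron],
        [Wire("stim.y", "neuron.I")],
        log=["stim.y", "neuron.V", "neuron.spike"],
    )
    logs = run_fixed_step(graph, cfg.duration, cfg.dt, cfg.seed)
    res = ProtocolResult(cfg, logs=logs)
    res.summary["mean_V"] = float(logs["neuron.V"].values.mean())
    res.summary["n_spikes"] = int(logs["neuron.spike"].values.sum())
    res.save()
    return res


def _conductance_clamp(cfg: ProtocolConfig) -> ProtocolResult:
    R_e, R_i = background_rates(
        cfg.params.get("background", "1x"), cfg.params.get("R_i")
    )
    graph = build_conductance_clamp_graph(
        cfg, R_e, R_i, I_ext=cfg.params.get("I_ext", 0.0)
    )
    logs = run_fixed_step(graph, cfg.duration, cfg.dt, cfg.seed)
    spikes = logs.spike_times("neuron.spike")
    res = ProtocolResult(cfg, logs=logs)
    v = logs["neuron.V"].values
    res.summary.update(
        R_e=R_e,
        R_i=R_i,
        mean_V=float(v.mean()),
        sd_V=float(v.std()),
        n_spikes=len(spikes),
        rate=len(spikes) / cfg.duration,
    )
    if len(spikes) >= 2:
        stats = analysis.isi_stats(spikes)
        res.summary["isi_cv"] = stats.cv
    res.save()
    return res


def _sine_modulated_background(cfg: ProtocolConfig) -> ProtocolResult:
    R_e, R_i = background_rates(
        cfg.params.get("background", "1x"), cfg.params.get("R_i")
    )
    f_mod = cfg.params.get("frequency", 100.0)
    mod = dict(
        frequency=f_mod,
        fraction=cfg.params.get("fraction", 0.1),
        channels=cfg.params.get("channels", "e"),
        filter_modulation=cfg.params.get("filter_modulation", True),
    )
    graph = build_conductance_clamp_graph(
        cfg, R_e, R_i, I_ext=cfg.params.get("I_ext", 0.0), mod=mod
    )
    logs = run_fixed_step(graph, cfg.duration, cfg.dt, cfg.seed)
    spikes = logs.spike_times("neuron.spike")
    period = 1.0 / f_mod
    hist = analysis.cycle_histogram(
        spikes, period, cfg.params.get("n_bins", 32), cfg.duration
    )
    fit = analysis.fit_rate_sinusoid(hist, 2.0 * math.pi / period)
    res = ProtocolResult(cfg, logs=logs)
    res.summary.update(
        R_e=R_e, R_i=R_i, n_spikes=len(spikes),
        r0=fit.r0, r1=fit.r1, phi=fit.phi,
    )
    res.save()
    return res


def _firing_rate_clamp(cfg: ProtocolConfig) -> ProtocolResult:
    R_e, R_i = background_rates(
        cfg.params.get("background", "1x"), cfg.params.get("R_i")
    )
    rc = dict(
        target=cfg.params.get("target", 17.0),
        P=cfg.params.get("P", 0.0045),
        I=cfg.params.get("I", 0.0023),
        D=cfg.params.get("D", 0.0),
        tau_r=cfg.params.get("tau_r", 1.0),
    )
    graph = build_conductance_clamp_graph(cfg, R_e, R_i, rate_clamp=rc)
    logs = run_fixed_step(graph, cfg.duration, cfg.dt, cfg.seed)
    spikes = logs.spike_times("neuron.spike")
    window = cfg.params.get("evaluation_window", 20.0)
    t_lo = max(cfg.duration - window, 0.0)
    n_win = np.sum(spikes >= t_lo)
    res = ProtocolResult(cfg, logs=logs)
    res.summary.update(
        R_e=R_e,
        R_i=R_i,
        target=rc["target"],
        n_spikes=len(spikes),
        mean_rate_final=float(n_win / (cfg.duration - t_lo)),
        mean_I_ext_final=float(
            logs["pid.I_ext"].values[int(t_lo / cfg.dt) :].mean()
        ),
    )
    res.save()
    return res


def _voltage_hold(cfg: ProtocolConfig) -> ProtocolResult:
    cfg = replace(cfg, preparation=cfg.params.get("preparation", "passive"))
    neuron = _neuron_block(cfg)
    hold = blocks.VoltageHold(
        "hold",
        V_target=cfg.params.get("V_target", -60e-3),
        P=cfg.params.get("P", 10.0),
        I=cfg.params.get("I", 100.0),
    )
    v_init = preparations.make_preparation(cfg.preparation, **cfg.overrides).E_L
    graph = BlockGraph(
        [neuron, hold],
        [
            Wire("neuron.V", "hold.V"),
            Wire("hold.I_hold", "neuron.I", feedback=True, init=0.0),
        ],
        constants={"hold.gate": 1.0},
        log=["neuron.V", "hold.I_hold"],
    )
    logs = run_fixed_step(graph, cfg.duration, cfg.dt, cfg.seed)
    v = logs["neuron.V"].values
    tail = v[int(0.8 * len(v)) :]
    res = ProtocolResult(cfg, logs=logs)
    res.summary.update(
        V_target=cfg.params.get("V_target", -60e-3),
        final_V=float(tail.mean()),
        final_error=float(abs(tail.mean() - cfg.params.get("V_target", -60e-3))),
    )
    res.save()
    return res


def fi_gain_experiment(
    cfg: ProtocolConfig,
    currents,
    scales=("0x", "1x", "2x", "3x"),
    duration: float = 5.0,
    transient: float = 0.5,
) -> dict[str, analysis.FICurve]:
    """Frequency-current curves under increasing background conductance.

    For each background scale the dynamic-clamp loop runs once per external
    current level; the suprathreshold slope quantifies the gain modulation
    (background conductance divisively reduces it).
    """
    out: dict[str, analysis.FICurve] = {}
    for scale in scales:
        R_e, R_i = background_rates(scale)
        spikes_per_level = []
        for j, I_ext in enumerate(currents):
            graph = build_conductance_clamp_graph(cfg, R_e, R_i, I_ext=float(I_ext))
            logs = run_fixed_step(graph, duration, cfg.dt, cfg.seed + 101 * j)
            spikes_per_level.append(logs.spike_times("neuron.spike"))
        out[scale] = analysis.fi_curve(
            currents, spikes_per_level, duration, transient, background_scale=scale
        )
    return out


# ---------------------------------------------------------------------------
# AEC support
# ---------------------------------------------------------------------------


def estimate_preparation_kernel(
    cfg: ProtocolConfig,
    electrode: preparations.ElectrodeParams,
    probe_amplitude: float = 100e-12,
    probe_duration: float = 10.0,
    kernel_length: float = 15e-3,
    tail_start: float = 1e-3,
    ridge: float = 0.0,
):
    """Run the uniform-noise probe through the simulated preparation and
    electrode and identify the electrode kernel.

    Returns ``(K_electrode, K_full, R_m, tau_m)``.
    """
    probe = generate_probe_current(probe_amplitude, probe_duration, cfg.dt, seed=cfg.seed)
    src = blocks.WaveformSource("probe", trace=probe)
    neuron = _neuron_block(cfg)
    el = blocks.Electrode("electrode", params=electrode)
    graph = BlockGraph(
        [src, neuron, el],
        [
            Wire("probe.y", "neuron.I"),
            Wire("probe.y", "electrode.I"),
            Wire("neuron.V", "electrode.V_m"),
        ],
        log=["probe.y", "electrode.V_rec"],
    )
    logs = run_fixed_step(graph, probe_duration, cfg.dt, cfg.seed)
    n_taps = int(round(kernel_length / cfg.dt))
    K_full = estimate_full_kernel(
        logs["probe.y"], logs["electrode.V_rec"], n_taps=n_taps, ridge=ridge
    )
    K_e, R_m, tau_m = split_electrode_kernel(K_full, membrane_tail_start=tail_start)
    return K_e, K_full, R_m, tau_m


# ---------------------------------------------------------------------------
# drift models and event-level protocols
# ---------------------------------------------------------------------------


@dataclass
class ExcitabilityDriftModel:
    """Synthetic stand-in for slowly drifting neuronal excitability.

    The probability of an antidromic spike at stimulus intensity ``S``
    (device units) is a sigmoidal recruitment curve
    ``p = 1/(1 + exp(-(S - theta)/width))`` whose threshold ``theta``
    performs an OU walk around ``theta0`` with time constant ``tau_drift``
    and stationary sd of 10% of the dynamic range (taken as 6*width, the
    5-95% span of the sigmoid).  All values are declared fixture
    parameters.
    """

    theta0: float = 300.0
    width: float = 30.0
    tau_drift: float = 120.0
    sd_fraction: float = 0.10
    theta_min: float = 50.0
    theta_max: float = 600.0

    @property
    def sd(self) -> float:
        return self.sd_fraction * 6.0 * self.width

    def spike_probability(self, S: float, theta: float) -> float:
        return 1.0 / (1.0 + math.exp(-(S - theta) / self.width))

    def advance(self, theta: float, dt_event: float, rng: np.random.Generator) -> float:
        """Exact OU transition over one inter-stimulus interval."""
        rho = math.exp(-dt_event / self.tau_drift)
        theta = (
            self.theta0
            + (theta - self.theta0) * rho
            + self.sd * math.sqrt(1.0 - rho * rho) * rng.standard_normal()
        )
        return min(max(theta, self.theta_min), self.theta_max)


@dataclass
class SynapticDriftModel:
    """Drifting synaptic pathway for the EPSP-size clamp.

    Stimulus intensity recruits presynaptic drive through a saturating
    curve ``W(S) = 1 - exp(-S/S_c)``; the evoked PSC feeds a
    Tsodyks-Markram synapse whose absolute efficacy is multiplied by a
    slow OU factor (mean 1, sd ``eff_sd``, time constant ``tau_drift``).
    ``A_syn`` is calibrated so a fully recruited, non-depressed, nominal-
    efficacy stimulus evokes a ~1 mV PSP in the passive preparation.
    """

    S_c: float = 300.0
    A_syn: float = 127e-12
    tau_drift: float = 120.0
    eff_sd: float = 0.15
    eff_min: float = 0.2

    def recruitment(self, S: float) -> float:
        return 1.0 - math.exp(-max(S, 0.0) / self.S_c)

    def advance(self, eff: float, dt_event: float, rng: np.random.Generator) -> float:
        rho = math.exp(-dt_event / self.tau_drift)
        eff = 1.0 + (eff - 1.0) * rho + self.eff_sd * math.sqrt(1.0 - rho * rho) * rng.standard_normal()
        return max(eff, self.eff_min)


# antidromic spike template for the event-level response windows
_AP_DURATION = 4e-3
_AP_LATENCY = 3e-3


def _spike_template(dt: float) -> np.ndarray:
    """Stylised action-potential waveform (rest-relative, volts)."""
    n = int(round(_AP_DURATION / dt))
    t = dt * np.arange(n)
    rise = np.exp(-((t - 0.8e-3) ** 2) / (2 * (0.35e-3) ** 2))
    ahp = -0.12 * np.exp(-((t - 2.2e-3) ** 2) / (2 * (0.8e-3) ** 2))
    return 100e-3 * rise + 40e-3 * ahp


def _response_window(
    responded: bool,
    dt: float,
    pre: float,
    post: float,
    v_rest: float,
    noise_sd: float,
    rng: np.random.Generator,
    trigger_time: float,
) -> TriggeredSegment:
    n = int(round((pre + post) / dt)) + 1
    v = v_rest + noise_sd * rng.standard_normal(n)
    if responded:
        i0 = int(round((pre + _AP_LATENCY) / dt))
        tpl = _spike_template(dt)
        v[i0 : i0 + len(tpl)] += tpl[: max(n - i0, 0)]
    seg = TriggeredSegment(trigger_time=trigger_time, pre_window=pre, post_window=post)
    seg.traces["V"] = Trace(dt=dt, values=v, unit="V", t0=trigger_time - pre)
    return seg


def _response_probability_clamp(cfg: ProtocolConfig) -> ProtocolResult:
    p = cfg.params
    n_stimuli = int(p.get("n_stimuli", 300))
    isi = float(p.get("ISI", 4.0))
    p_target = float(p.get("p_target", 0.5))
    tau = float(p.get("tau", 600.0))
    drift = p.get("drift_model") or ExcitabilityDriftModel()
    window_dt = float(p.get("window_dt", 1e-4))
    pre, post = 10e-3, 500e-3
    detector = controllers.SpikeDetectorParams(threshold=-20e-3, refractory=2e-3)

    rng_drift = np.random.default_rng([cfg.seed, 1])
    rng_resp = np.random.default_rng([cfg.seed, 2])
    rng_noise = np.random.default_rng([cfg.seed, 3])

    prob = controllers.ProbabilityState(
        tau=tau, ISI=isi, p=float(p.get("p0", p_target))
    )
    ctrl = controllers.StimulusControllerState(
        S_1=float(p.get("S_1", drift.theta0)),
        G=float(p.get("G", 700.0)),
        P_pid=float(p.get("P_pid", 1.0)),
        I_pid=float(p.get("I_pid", 0.3)),
        target=p_target,
        bounds=p.get("bounds", (0.0, 2.0 * drift.theta_max)),
    )
    pulse_width = float(p.get("phase_width", 200e-6))

    theta = drift.theta0
    S = ctrl.S_1
    rows = []
    segments: list[TriggeredSegment] = []
    keep_segments = bool(p.get("keep_segments", False))
    for n in range(n_stimuli):
        t_n = (n + 1) * isi
        theta = drift.advance(theta, isi, rng_drift)
        p_spike = drift.spike_probability(S, theta)
        responded_true = rng_resp.uniform() < p_spike
        seg = _response_window(
            responded_true, window_dt, pre, post, -70e-3, 0.5e-3, rng_noise, t_n
        )
        spk = controllers.detect_spikes(
            seg.traces["V"], replace(detector, window=(t_n, t_n + post))
        )
        responded = len(spk) >= 1
        controllers.update_response_probability(prob, responded)
        rows.append(
            dict(
                n=n, time=t_n, S=S, theta=theta, p_true=p_spike,
                responded=int(responded), p_est=prob.p,
                phase_width=pulse_width,
            )
        )
        if keep_segments:
            segments.append(seg)
        S = controllers.next_stimulus_intensity(ctrl, prob.p)

    events = pd.DataFrame(rows)
    discard = int(p.get("discard", 50))
    locked = events.iloc[discard:]
    dev = np.abs(locked["p_est"].to_numpy() - p_target) / p_target
    res = ProtocolResult(cfg, events=events, segments=segments)
    res.summary.update(
        p_target=p_target,
        mean_p=float(locked["p_est"].mean()),
        mean_rel_dev_pct=float(100.0 * dev.mean()),
        var_p=float(locked["p_est"].var()),
        n_clipped=ctrl.clipped,
    )
    res.save()
    return res


def replay_open_loop(recorded: pd.DataFrame, cfg: ProtocolConfig) -> ProtocolResult:
    """Deliver a recorded stimulus sequence without feedback.

    The drift, response and noise streams are seeded from ``cfg.seed`` with
    the same family as the closed-loop run, so replaying with the closed-loop
    seed against the frozen preparation reproduces the responses exactly,
    while a different seed gives a fresh drift realisation.  Reports the
    probability-estimate variance for closed/open-loop comparison.
    """
    p = cfg.params
    if "S" not in recorded.columns:
        raise ValueError("event table lacks the stimulus-intensity column 'S'")
    isi = float(p.get("ISI", 4.0))
    tau = float(p.get("tau", 600.0))
    p_target = float(p.get("p_target", 0.5))
    drift = p.get("drift_model") or ExcitabilityDriftModel()
    window_dt = float(p.get("window_dt", 1e-4))
    pre, post = 10e-3, 500e-3
    detector = controllers.SpikeDetectorParams(threshold=-20e-3, refractory=2e-3)

    rng_drift = np.random.default_rng([cfg.seed, 1])
    rng_resp = np.random.default_rng([cfg.seed, 2])
    rng_noise = np.random.default_rng([cfg.seed, 3])
    prob = controllers.ProbabilityState(tau=tau, ISI=isi, p=float(p.get("p0", p_target)))

    theta = drift.theta0
    rows = []
    for n, S in enumerate(recorded["S"].to_numpy()):
        t_n = (n + 1) * isi
        theta = drift.advance(theta, isi, rng_drift)
        p_spike = drift.spike_probability(float(S), theta)
        responded_true = rng_resp.uniform() < p_spike
        seg = _response_window(
            responded_true, window_dt, pre, post, -70e-3, 0.5e-3, rng_noise, t_n
        )
        spk = controllers.detect_spikes(
            seg.traces["V"], replace(detector, window=(t_n, t_n + post))
        )
        responded = len(spk) >= 1
        controllers.update_response_probability(prob, responded)
        rows.append(
            dict(n=n, time=t_n, S=float(S), theta=theta, responded=int(responded), p_est=prob.p)
        )
    events = pd.DataFrame(rows)
    discard = int(p.get("discard", 50))
    locked = events.iloc[discard:] if len(events) > discard else events
    res = ProtocolResult(cfg, events=events)
    res.summary.update(
        p_target=p_target,
        var_p=float(locked["p_est"].var()) if len(locked) else float("nan"),
        mean_p=float(locked["p_est"].mean()) if len(locked) else float("nan"),
    )
    res.save()
    return res


def _simulate_psp_window(
    drive: float,
    syn_params: preparations.TMSynapseParams,
    syn_state: preparations.PreparationState,
    dt: float,
    pre: float,
    post: float,
    noise_sd: float,
    rng: np.random.Generator,
    trigger_time: float,
) -> TriggeredSegment:
    """Euler simulation of the passive membrane receiving one evoked PSC.

    ``drive`` multiplies the synaptic efficacy (recruitment x slow drift);
    the TM state carries short-term depression across stimuli.
    """
    mem = preparations.passive_params()
    mst = preparations.init_state(mem)
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    v = np.empty(n_pre + n_post + 1)
    params = replace(syn_params, A=syn_params.A * drive)
    for i in range(n_pre + n_post + 1):
        presyn = i == n_pre
        syn_state, psc = preparations.step_tm_synapse(params, syn_state, presyn, dt)
        mst, _ = preparations.step_point_neuron(mem, mst, psc, dt)
        v[i] = mst.V
    v += noise_sd * rng.standard_normal(len(v))
    seg = TriggeredSegment(trigger_time=trigger_time, pre_window=pre, post_window=post)
    seg.traces["V"] = Trace(dt=dt, values=v, unit="V", t0=trigger_time - pre)
    return seg


def _epsp_size_clamp(cfg: ProtocolConfig) -> ProtocolResult:
    p = cfg.params
    n_stimuli = int(p.get("n_stimuli", 300))
    isi = float(p.get("ISI", 4.0))
    target = float(p.get("target", 0.5e-3))  # volts
    tau = float(p.get("tau", 300.0))
    drift = p.get("drift_model") or SynapticDriftModel()
    syn = p.get("synapse") or preparations.TMSynapseParams(
        U=0.5, tau_rec=0.5, tau_facil=0.0, A=drift.A_syn, tau_syn=5e-3
    )
    window_dt = float(p.get("window_dt", 2e-4))
    pre, post = 10e-3, 300e-3
    baseline_w, search_w = 10e-3, 100e-3
    err_scale = float(p.get("error_scale", 1e3))  # controller works in mV

    rng_drift = np.random.default_rng([cfg.seed, 11])
    rng_noise = np.random.default_rng([cfg.seed, 12])

    est = controllers.ProbabilityState(
        tau=tau, ISI=isi, p=float(p.get("A0", target)), bounded=False
    )
    S_1 = float(p.get("S_1", -drift.S_c * math.log(0.5)))  # nominal 0.5 mV point
    ctrl = controllers.StimulusControllerState(
        S_1=S_1,
        G=float(p.get("G", 1600.0)),
        P_pid=float(p.get("P_pid", 1.0)),
        I_pid=float(p.get("I_pid", 0.3)),
        target=target * err_scale,
        bounds=p.get("bounds", (0.0, 5000.0)),
    )

    eff = 1.0
    S = ctrl.S_1
    syn_state = preparations.PreparationState(u=0.0, x=1.0, psc=0.0)
    rows = []
    segments: list[TriggeredSegment] = []
    keep_segments = bool(p.get("keep_segments", False))
    for n in range(n_stimuli):
        t_n = (n + 1) * isi
        eff = drift.advance(eff, isi, rng_drift)
        drive = drift.recruitment(S) * eff
        seg = _simulate_psp_window(
            drive, syn, syn_state, window_dt, pre, post, 0.02e-3, rng_noise, t_n
        )
        amp = controllers.measure_psp_amplitude(seg, baseline_w, search_w, "positive")
        controllers.update_response_probability(est, amp)
        rows.append(
            dict(n=n, time=t_n, S=S, efficacy=eff, amplitude=amp, A_est=est.p)
        )
        if keep_segments:
            segments.append(seg)
        S = controllers.next_stimulus_intensity(ctrl, est.p * err_scale)

    events = pd.DataFrame(rows)
    discard = int(p.get("discard", 50))
    locked = events.iloc[discard:]
    rel = np.abs(locked["A_est"].to_numpy() - target) / target
    res = ProtocolResult(cfg, events=events, segments=segments)
    res.summary.update(
        target_V=target,
        mean_amplitude=float(locked["amplitude"].mean()),
        mean_A_est=float(locked["A_est"].mean()),
        mean_rel_dev_pct=float(100.0 * rel.mean()),
        n_clipped=ctrl.clipped,
    )
    res.save()
    return res


# ---------------------------------------------------------------------------
# registry, runner, fixtures
# ---------------------------------------------------------------------------

PROTOCOLS = {
    "arbitrary_stream_and_record": _arbitrary_stream_and_record,
    "conductance_clamp": _conductance_clamp,
    "sine_modulated_background": _sine_modulated_background,
    "firing_rate_clamp": _firing_rate_clamp,
    "voltage_hold": _voltage_hold,
    "response_probability_clamp": _response_probability_clamp,
    "epsp_size_clamp": _epsp_size_clamp,
}


def run_protocol(config: ProtocolConfig) -> ProtocolResult:
    """Dispatch a configured protocol run and return its artifacts."""
    if config.protocol not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {config.protocol!r}; registered: {sorted(PROTOCOLS)}"
        )
    try:
        return PROTOCOLS[config.protocol](config)
    except Exception as e:
        raise type(e)(f"[protocol {config.protocol}] {e}") from e


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> dict:
    """Deterministic test fixtures with ground-truth manifests.

    Kinds: ``probe_circuit`` (paired probe current / recorded voltage with
    known electrode+membrane), ``drift_neuron`` (threshold trajectory of
    the excitability drift model), ``poisson_modulated_spikes``
    (inhomogeneous Poisson spike times with known r0/r1/phase) and
    ``psp_segments`` (triggered segments with known PSP amplitudes).
    Returns a dict of arrays/objects plus a ``manifest`` of true parameters.
    """
    params = dict(params or {})
    if kind == "probe_circuit":
        R_s = params.get("R_s", 10e6)
        C_e = params.get("C_e", 1e-12)
        dt = params.get("dt", 5e-5)
        duration = params.get("duration", 10.0)
        amplitude = params.get("amplitude", 100e-12)
        cfg = ProtocolConfig(
            protocol="arbitrary_stream_and_record",
            preparation=params.get("preparation", "passive"),
            dt=dt,
            seed=seed,
        )
        electrode = preparations.ElectrodeParams(R_s=R_s, C_e=C_e)
        probe = generate_probe_current(amplitude, duration, dt, seed=seed)
        src = blocks.WaveformSource("probe", trace=probe)
        neuron = _neuron_block(cfg)
        el = blocks.Electrode("electrode", params=electrode)
        graph = BlockGraph(
            [src, neuron, el],
            [
                Wire("probe.y", "neuron.I"),
                Wire("probe.y", "electrode.I"),
                Wire("neuron.V", "electrode.V_m"),
            ],
            log=["probe.y", "electrode.V_rec", "neuron.V"],
        )
        logs = run_fixed_step(graph, duration, dt, seed)
        mem = preparations.make_preparation(cfg.preparation)
        return dict(
            I=logs["probe.y"],
            V_rec=logs["electrode.V_rec"],
            V_m=logs["neuron.V"],
            manifest=dict(
                R_s=R_s, C_e=C_e, R_m=1.0 / mem.g_L, tau_m=mem.C / mem.g_L,
                dt=dt, seed=seed,
            ),
        )
    if kind == "drift_neuron":
        drift = ExcitabilityDriftModel(**params.pop("model", {}))
        n = int(params.get("n_events", 300))
        isi = float(params.get("ISI", 4.0))
        rng = np.random.default_rng([seed, 1])
        theta = np.empty(n)
        th = drift.theta0
        for i in range(n):
            th = drift.advance(th, isi, rng)
            theta[i] = th
        return dict(theta=theta, manifest=dict(**drift.__dict__, ISI=isi, seed=seed))
    if kind == "poisson_modulated_spikes":
        r0 = float(params.get("r0", 10.0))
        r1 = float(params.get("r1", 3.0))
        f = float(params.get("frequency", 100.0))
        phase = float(params.get("phase", 0.0))
        n_cycles = int(params.get("n_cycles", 10000))
        T = n_cycles / f
        rng = np.random.default_rng(seed)
        r_max = r0 + r1
        n_cand = rng.poisson(r_max * T)
        t_cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        rate = r0 + r1 * np.sin(2.0 * math.pi * f * t_cand + phase)
        keep = rng.uniform(0.0, r_max, size=n_cand) < rate
        spikes = t_cand[keep]
        return dict(
            spikes=spikes,
            manifest=dict(r0=r0, r1=r1, frequency=f, phase=phase, n_cycles=n_cycles, seed=seed),
        )
    if kind == "psp_segments":
        n_seg = int(params.get("n_segments", 10))
        amp = float(params.get("amplitude", 0.5e-3))
        drift_slope = float(params.get("baseline_drift", 0.0))  # V/s
        dt = float(params.get("dt", 2e-4))
        pre, post = 10e-3, 300e-3
        tau_m, tau_s = 20e-3, 5e-3
        rng = np.random.default_rng(seed)
        segs = []
        for i in range(n_seg):
            n = int(round((pre + post) / dt)) + 1
            t = dt * np.arange(n) - pre
            shape = np.where(
                t > 0, np.exp(-np.maximum(t, 0) / tau_m) - np.exp(-np.maximum(t, 0) / tau_s), 0.0
            )
            shape /= shape.max()
            v = -70e-3 + amp * shape + drift_slope * (t + pre)
            seg = TriggeredSegment(trigger_time=(i + 1.0), pre_window=pre, post_window=post)
            seg.traces["V"] = Trace(dt=dt, values=v, unit="V", t0=(i + 1.0) - pre)
            segs.append(seg)
        return dict(segments=segs, manifest=dict(amplitude=amp, baseline_drift=drift_slope, dt=dt))
    raise KeyError(f"unknown fixture kind {kind!r}")
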