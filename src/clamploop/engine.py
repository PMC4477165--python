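"""Fixed-time-step block-graph executor.

The engine mirrors the composition model of block-diagram environments used
for real-time electrophysiology rigs: named processing blocks expose typed
input/output ports, directed wires carry one sample per step, and closed
loops must be declared explicitly as *feedback* wires carrying a one-step
delay (sample-and-hold semantics) with a stated initial value.  Algebraic
loops are rejected rather than solved.

Execution is deterministic: blocks fire in a fixed topological order computed
over the non-feedback wires, model time is derived as ``t = n*dt`` (never
accumulated), and every stochastic block draws from an independent child
stream keyed by its block name, so adding a block never perturbs the noise
seen by the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np

from .trace import Trace, TriggeredSegment


class EngineError(RuntimeError):
    """Graph validation or runtime failure."""


class NonFiniteError(EngineError):
    """A block produced a non-finite output (instability detector).

    Carries the offending block name and the step index at which the
    non-finite value appeared.
    """

    def __init__(self, block: str, port: str, step: int):
        self.block = block
        self.port = port
        self.step = step
        super().__init__(
            f"non-finite value on {block}.{port} at step {step}; "
            "the simulation is numerically unstable"
        )


class Block:
    """Base class for processing blocks.

    Subclasses declare ``in_ports`` / ``out_ports`` and implement
    :meth:`step`, which receives the model time and a dict of input samples
    and returns a dict of output samples.  ``stochastic = True`` blocks are
    handed an independent :class:`numpy.random.Generator` in :meth:`reset`.
    """

    in_ports: tuple[str, ...] = ()
    out_ports: tuple[str, ...] = ()
    stochastic: bool = False

    def __init__(self, name: str):
        self.name = name

    def reset(self, dt: float, rng: np.random.Generator | None) -> None:
        """Prepare internal state for a run at step ``dt``."""

    def step(self, t: float, inputs: dict) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} {self.name!r}>"


@dataclass(frozen=True)
class Wire:
    """Directed connection ``src_block.src_port -> dst_block.dst_port``.

    ``feedback=True`` inserts a unit-delay register initialised to ``init``;
    the destination reads the source's value from the *previous* step.
    """

    src: str  # "block.port"
    dst: str  # "block.port"
    feedback: bool = False
    init: float = 0.0


def _split(ref: str) -> tuple[str, str]:
    block, _, port = ref.partition(".")
    if not port:
        raise EngineError(f"port reference {ref!r} must be 'block.port'")
    return block, port


def _child_rng(seed: int, name: str) -> np.random.Generator:
    # Stable per-block stream: spawn key derived from the block name only,
    # so renumbering or adding unrelated blocks leaves this stream intact.
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


class BlockGraph:
    """A validated wiring of blocks plus logging channels."""

    def __init__(
        self,
        blocks: list[Block],
        wires: list[Wire],
        constants: dict[str, float] | None = None,
        log: list[str] | None = None,
    ):
        self.blocks: dict[str, Block] = {}
        for b in blocks:
            if b.name in self.blocks:
                raise EngineError(f"duplicate block name {b.name!r}")
            self.blocks[b.name] = b
        self.wires = list(wires)
        self.constants = dict(constants or {})
        self.log = list(log or [])
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for ref in list(self.constants):
            blk, port = _split(ref)
            self._require_port(blk, port, "in")
        fed: dict[str, Wire] = {}
        for w in self.wires:
            sb, sp = _split(w.src)
            db, dp = _split(w.dst)
            self._require_port(sb, sp, "out")
            self._require_port(db, dp, "in")
            if w.dst in fed:
                raise EngineError(f"input port {w.dst} has more than one incoming wire")
            if w.dst in self.constants:
                raise EngineError(f"input port {w.dst} is wired and also has a constant")
            fed[w.dst] = w
        for name, blk in self.blocks.items():
            for port in blk.in_ports:
                ref = f"{name}.{port}"
                if ref not in fed and ref not in self.constants:
                    raise EngineError(f"dangling input port {ref} (no wire, no constant)")
        # acyclicity over non-feedback wires
        ts: TopologicalSorter = TopologicalSorter()
        for name in self.blocks:
            ts.add(name)
        for w in self.wires:
            if not w.feedback:
                ts.add(_split(w.dst)[0], _split(w.src)[0])
        try:
            self.order = list(ts.static_order())
        except CycleError as e:
            raise EngineError(
                "wiring contains a cycle not broken by any feedback edge: "
                f"{e.args[1]}; declare one wire of the loop as feedback with an "
                "initial value"
            ) from None

    def _require_port(self, block: str, port: str, kind: str) -> None:
        if block not in self.blocks:
            raise EngineError(f"unknown block {block!r}")
        ports = self.blocks[block].in_ports if kind == "in" else self.blocks[block].out_ports
        if port not in ports:
            raise EngineError(f"block {block!r} has no {kind}put port {port!r}")


class LogStore(dict):
    """Run output: channel name -> :class:`Trace`, plus run metadata."""

    def __init__(self, *args, dt: float = 0.0, seed: int | None = None, **kw):
        super().__init__(*args, **kw)
        self.dt = dt
        self.seed = seed

    def spike_times(self, channel: str) -> np.ndarray:
        """Times at which a logged 0/1 event flag channel is nonzero."""
        tr = self[channel]
        idx = np.nonzero(tr.values > 0.5)[0]
        return tr.t0 + idx * tr.dt


def run_fixed_step(
    graph: BlockGraph,
    duration: float,
    dt: float,
    seed: int = 0,
) -> LogStore:
    """Execute ``floor(duration/dt)`` steps of the graph and return the logs.

    Within one step, blocks fire in topological order; feedback wires deliver
    the source value from the previous step (their register's initial value
    at step 0).  Identical ``(graph, seed)`` pairs yield bit-identical logs.

    Raises :class:`NonFiniteError` as soon as any block emits a non-finite
    sample, naming the block and the step index.
    """
    if duration <= 0 or dt <= 0:
        raise EngineError("duration and dt must be positive")
    n_steps = int(math.floor(duration / dt + 1e-9))

    for name, blk in graph.blocks.items():
        blk.reset(dt, _child_rng(seed, name) if blk.stochastic else None)

    # Execution plan: for each block, how to assemble its input dict.
    values: dict[str, float] = dict(graph.constants)
    registers: dict[str, float] = {}
    fb_sources: list[tuple[str, str]] = []  # (register key == dst ref, src ref)
    direct: dict[str, list[tuple[str, str]]] = {n: [] for n in graph.blocks}
    fback: dict[str, list[tuple[str, str]]] = {n: [] for n in graph.blocks}
    const_in: dict[str, list[tuple[str, float]]] = {n: [] for n in graph.blocks}
    for ref, val in graph.constants.items():
        b, p = _split(ref)
        const_in[b].append((p, float(val)))
    for w in graph.wires:
        db, dp = _split(w.dst)
        if w.feedback:
            registers[w.dst] = float(w.init)
            fb_sources.append((w.dst, w.src))
            fback[db].append((dp, w.dst))
        else:
            direct[db].append((dp, w.src))
    plan = [
        (graph.blocks[n], direct[n], fback[n], const_in[n], n)
        for n in graph.order
    ]

    log_keys = list(graph.log)
    for ref in log_keys:
        b, p = _split(ref)
        graph._require_port(b, p, "out")
    log_arrays = {k: np.empty(n_steps) for k in log_keys}

    isfinite = math.isfinite
    for n in range(n_steps):
        t = n * dt
        for blk, ins, fbs, consts, name in plan:
            inputs = {p: values[k] for p, k in ins}
            for p, rk in fbs:
                inputs[p] = registers[rk]
            for p, v in consts:
                inputs[p] = v
            out = blk.step(t, inputs)
            for p, v in out.items():
                if not isfinite(v):
                    raise NonFiniteError(name, p, n)
                values[f"{name}.{p}"] = v
        for rk, src in fb_sources:
            registers[rk] = values[src]
        for k, arr in log_arrays.items():
            arr[n] = values[k]

    store = LogStore(dt=dt, seed=seed)
    for k, arr in log_arrays.items():
        store[k] = Trace(dt=dt, values=arr, unit=_log_unit(graph, k))
    return store


def _log_unit(graph: BlockGraph, ref: str) -> str:
    b, p = _split(ref)
    units = getattr(graph.blocks[b], "port_units", {})
    return units.get(p, "1")


def build_graph(spec: dict) -> BlockGraph:
    """Build a validated :class:`BlockGraph` from a protocol configuration dict.

    ``spec`` uses the flat structure read from a protocol file::

        blocks:   {name: {kind: ..., params: {...}}, ...}
        wires:    [{from: "a.y", to: "b.x", feedback: false, init: 0.0}, ...]
        constants: {"b.u": 0.0, ...}
        log:      ["a.y", ...]

    Unknown block kinds, dangling ports and undeclared cycles are rejected.
    """
    from .blocks import BLOCK_REGISTRY  # late import: blocks depends on engine

    blocks = []
    for name, bs in (spec.get("blocks") or {}).items():
        kind = bs.get("kind")
        if kind not in BLOCK_REGISTRY:
            raise EngineError(f"unknown block kind {kind!r} for block {name!r}")
        blocks.append(BLOCK_REGISTRY[kind](name, **(bs.get("params") or {})))
    wires = [
        Wire(
            src=w["from"],
            dst=w["to"],
            feedback=bool(w.get("feedback", False)),
            init=float(w.get("init", 0.0)),
        )
        for w in (spec.get("wires") or [])
    ]
    return BlockGraph(
        blocks,
        wires,
        constants=spec.get("constants"),
        log=spec.get("log"),
    )


def segment_logger(
    trigger_events,
    channels: dict[str, Trace],
    pre_window: float,
    post_window: float,
) -> tuple[list[TriggeredSegment], list[float]]:
    """Cut triggered segments out of continuous channels.

    Emulates triggered data logging: instead of storing the whole stream,
    each trigger produces copies of every channel spanning
    ``[trigger - pre_window, trigger + post_window]`` inclusive of both
    endpoints.  Triggers whose window would leave the recording are skipped
    and reported in the second return value rather than raising.
    """
    if pre_window < 0 or post_window < 0:
        raise ValueError("windows must be non-negative")
    if not channels:
        return [], list(trigger_events)
    dts = {round(tr.dt, 15) for tr in channels.values()}
    if len(dts) > 1:
        raise ValueError("all channels must share the same dt")
    dt = next(iter(channels.values())).dt
    t0 = next(iter(channels.values())).t0
    n = min(len(tr) for tr in channels.values())

    segments: list[TriggeredSegment] = []
    skipped: list[float] = []
    n_pre = int(round(pre_window / dt))
    n_post = int(round(post_window / dt))
    for tt in sorted(trigger_events):
        i = int(round((tt - t0) / dt))
        lo, hi = i - n_pre, i + n_post
        if lo < 0 or hi >= n:
            skipped.append(tt)
            continue
        seg = TriggeredSegment(trigger_time=tt, pre_window=pre_window, post_window=post_window)
        for name, tr in channels.items():
            seg.traces[name] = Trace(
                dt=dt,
                values=tr.values[lo : hi + 1].copy(),
                unit=tr.unit,
                t0=tt - pre_window,
            )
        segments.append(seg)
    return segments, skipped
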