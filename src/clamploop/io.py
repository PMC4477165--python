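"""Text-format persistence for runs: log stores, stimulation event files and
triggered segments.

One tabular time-series file per run (columns: time plus named channels;
header comments record dt, seed and units); stimulation events as one row
per stimulus; triggered segments as separate files named by trigger index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import LogStore
from .trace import Trace, TriggeredSegment


def write_log_store(path, store: LogStore) -> None:
    path = Path(path)
    channels = list(store.keys())
    n = min(len(store[c]) for c in channels) if channels else 0
    dt = store.dt
    cols = {"time": dt * np.arange(n)}
    for c in channels:
        cols[c] = store[c].values[:n]
    units = ",".join(f"{c}={store[c].unit}" for c in channels)
    header = f"# dt={dt!r} seed={store.seed!r} units={units}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_log_store(path) -> LogStore:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
        df = pd.read_csv(fh, sep="\t")
    dt = float(meta.get("dt", "0") or 0) or float(df["time"].iloc[1] - df["time"].iloc[0])
    seed = meta.get("seed")
    seed = None if seed in (None, "None", "") else int(seed)
    units = dict(
        kv.split("=") for kv in meta.get("units", "").split(",") if "=" in kv
    )
    store = LogStore(dt=dt, seed=seed)
    for c in df.columns:
        if c == "time":
            continue
        store[c] = Trace(dt=dt, values=df[c].to_numpy(), unit=units.get(c, "1"))
    return store


def write_events(path, events: pd.DataFrame) -> None:
    """Stimulation events: one row per stimulus (time, amplitude, ...)."""
    events.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments(out_dir, segments: list[TriggeredSegment], stem: str = "segment") -> list[Path]:
    """One file per triggered segment, named by trigger index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, seg in enumerate(segments):
        p = out_dir / f"{stem}_{i:04d}.tsv"
        names = list(seg.traces)
        tr0 = seg.traces[names[0]]
        cols = {"time": tr0.times}
        for nm in names:
            cols[nm] = seg.traces[nm].values
        with open(p, "w") as fh:
            fh.write(
                f"# trigger_time={seg.trigger_time!r} pre={seg.pre_window!r} "
                f"post={seg.post_window!r} dt={tr0.dt!r}\n"
            )
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.9g")
        paths.append(p)
    return paths
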