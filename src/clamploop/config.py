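"""Protocol configuration files.

Flat structured text (YAML) naming the protocol (or a raw block graph),
preparation, parameters, duration, dt and seed.  Internally everything is
SI; quantities in config files may be written with units ("0.2 nS",
"-70 mV", "100 pA") and are converted at this boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

from .protocols import ProtocolConfig

_PREFIX = {
    "G": 1e9, "M": 1e6, "k": 1e3, "": 1.0,
    "m": 1e-3, "u": 1e-6, "µ": 1e-6, "n": 1e-9, "p": 1e-12, "f": 1e-15,
}
_BASE_UNITS = ("V", "A", "S", "F", "Hz", "s", "Ohm")

_QTY_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*"
    r"(G|M|k|m|u|µ|n|p|f)?(V|A|S|F|Hz|s|Ohm)\s*$"
)


def parse_quantity(value):
    """Convert "10 nS" style strings to SI floats; pass numbers through."""
    if isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if m:
            num, prefix, _unit = m.groups()
            return float(num) * _PREFIX[prefix or ""]
    return value


def _convert(obj):
    if isinstance(obj, dict):
        return {k: _convert(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_convert(v) for v in obj]
    return parse_quantity(obj)


def load_config(path) -> dict:
    """Read a YAML config, converting unit-tagged quantities to SI."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _convert(raw)


def protocol_config_from_file(path, **cli_overrides) -> ProtocolConfig:
    """Build a :class:`ProtocolConfig` from a file plus CLI overrides
    (duration, dt, seed, out_dir)."""
    data = load_config(path)
    if "protocol" not in data:
        raise ValueError(f"{path}: config lacks a 'protocol' entry")
    kw = dict(
        protocol=data["protocol"],
        duration=float(data.get("duration", 10.0)),
        dt=float(data.get("dt", 5e-5)),
        seed=int(data.get("seed", 0)),
        preparation=data.get("preparation", "l5_aeif"),
        overrides=data.get("overrides", {}) or {},
        params=data.get("params", {}) or {},
        out_dir=data.get("out_dir"),
    )
    for k, v in cli_overrides.items():
        if v is not None:
            kw[k] = v
    return ProtocolConfig(**kw)


def write_config(path, cfg: ProtocolConfig) -> None:
    data = dict(
        protocol=cfg.protocol,
        duration=cfg.duration,
        dt=cfg.dt,
        seed=cfg.seed,
        preparation=cfg.preparation,
        overrides=cfg.overrides,
        params={k: v for k, v in cfg.params.items() if isinstance(v, (int, float, str, list, dict))},
        out_dir=cfg.out_dir,
    )
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
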