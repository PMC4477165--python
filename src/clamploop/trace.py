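"""Uniformly sampled time series and triggered recording segments.

All quantities are SI internally (volts, amperes, siemens, seconds, hertz).
Configuration files may use mV / pA / nS; conversion happens at the config
boundary (:mod:`clamploop.config`), never inside the simulation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised physical unit tags for a trace.
UNITS = ("V", "A", "S", "Hz", "s", "1")


@dataclass
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds, strictly positive.
    values : numpy.ndarray
        Ordered samples (1-D).
    unit : str
        One of :data:`UNITS` ("1" marks a dimensionless signal).
    t0 : float
        Time of the first sample, seconds.
    """

    dt: float
    values: np.ndarray
    unit: str = "1"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + n*dt`` (derived, never accumulated)."""
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        return self.dt * len(self.values)

    def copy(self) -> "Trace":
        return Trace(self.dt, self.values.copy(), self.unit, self.t0)


@dataclass
class TriggeredSegment:
    """Traces cut around a trigger, spanning [trigger - pre, trigger + post].

    Each trace in ``traces`` has ``t0 = trigger_time - pre_window`` and covers
    the window inclusive of both endpoints.
    """

    trigger_time: float
    pre_window: float
    post_window: float
    traces: dict[str, Trace] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pre_window < 0 or self.post_window < 0:
            raise ValueError("pre/post windows must be non-negative")
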