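"""Off-line analyses of logged runs.

Cycle (peristimulus) histograms of spike times folded on the period of a
sinusoidal input, sinusoidal transfer fits r(t) = r0 + r1*sin(w*t + phi),
frequency-current curves with suprathreshold slope (gain) estimation, and
inter-spike-interval statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CycleHistogram:
    """Spike rate per phase bin, accumulated over whole stimulus cycles."""

    n_bins: int
    period: float
    bin_rates: np.ndarray
    counts: np.ndarray
    n_trials: int  # whole cycles accumulated

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times within one cycle (s)."""
        w = self.period / self.n_bins
        return w * (np.arange(self.n_bins) + 0.5)


@dataclass
class SinusoidFit:
    """Mean rate r0 (Hz), modulation amplitude r1 >= 0 (Hz), phase phi in
    (-pi, pi] (rad) and the residual RMS of the fit."""

    r0: float
    r1: float
    phi: float
    goodness: float
    degenerate: bool = False


@dataclass
class FICurve:
    currents: np.ndarray
    rates: np.ndarray
    background_scale: str = ""
    slope: float = float("nan")  # Hz/A over the suprathreshold range
    suprathreshold: np.ndarray = field(default=None)  # type: ignore[assignment]


def cycle_histogram(
    spikes: np.ndarray, period: float, n_bins: int, total_time: float
) -> CycleHistogram:
    """Fold spike times modulo the period into a rate-per-bin histogram.

    Only spikes inside whole cycles (t < n_cycles*period) are counted, so
    the total count is an exact integer invariant.  ``bin_rates`` are
    counts / (n_cycles * bin_width), i.e. trial-averaged rates in Hz.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    if total_time < period:
        raise ValueError("total_time must cover at least one period")
    spikes = np.asarray(spikes, dtype=float)
    n_cycles = int(math.floor(total_time / period + 1e-9))
    spikes = spikes[(spikes >= 0) & (spikes < n_cycles * period)]
    phase = np.mod(spikes, period)
    counts, _ = np.histogram(phase, bins=n_bins, range=(0.0, period))
    bin_width = period / n_bins
    rates = counts / (n_cycles * bin_width)
    return CycleHistogram(
        n_bins=n_bins, period=period, bin_rates=rates, counts=counts, n_trials=n_cycles
    )


def fit_rate_sinusoid(hist: CycleHistogram, omega: float) -> SinusoidFit:
    """Least-squares fit of r0 + r1*sin(omega*t + phi) to the bin rates.

    ``omega`` must be consistent with the histogram period (2*pi/period).
    The fit is linear in (r0, a, b) with r(t) = r0 + a*sin(wt) + b*cos(wt);
    r1 = hypot(a, b) is reported non-negative with phi wrapped accordingly.
    A flat histogram yields r1 = 0 with phi reported as 0 and the
    ``degenerate`` flag set.
    """
    if not math.isclose(omega, 2.0 * math.pi / hist.period, rel_tol=1e-6):
        raise ValueError("omega inconsistent with the histogram period")
    t = hist.bin_centers
    y = hist.bin_rates
    if np.allclose(y, y[0]):
        return SinusoidFit(r0=float(y[0]), r1=0.0, phi=0.0, goodness=0.0, degenerate=True)
    X = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    (r0, a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    r1 = math.hypot(a, b)
    phi = math.atan2(b, a)
    if phi <= -math.pi:
        phi += 2.0 * math.pi
    resid = y - X @ np.array([r0, a, b])
    return SinusoidFit(
        r0=float(r0), r1=float(r1), phi=float(phi), goodness=float(np.sqrt(np.mean(resid**2)))
    )


def fi_curve(
    currents,
    spike_times_per_level,
    duration: float,
    transient: float = 0.5,
    background_scale: str = "",
) -> FICurve:
    """Stationary rate per current level and the suprathreshold F-I slope.

    Spikes within the onset ``transient`` are discarded; the slope is the
    least-squares gain (Hz/A) over levels with a nonzero stationary rate.
    With no suprathreshold level the slope is left NaN (flagged by the
    caller inspecting ``suprathreshold``).
    """
    currents = np.asarray(currents, dtype=float)
    if len(currents) < 3:
        raise ValueError("need at least 3 current levels")
    if np.any(np.diff(currents) <= 0):
        raise ValueError("currents must be strictly increasing")
    if duration <= transient:
        raise ValueError("duration must exceed the discarded transient")
    rates = []
    for spikes in spike_times_per_level:
        spikes = np.asarray(spikes, dtype=float)
        rates.append(np.sum(spikes >= transient) / (duration - transient))
    rates = np.asarray(rates)
    supra = rates > 0
    fi = FICurve(
        currents=currents,
        rates=rates,
        background_scale=background_scale,
        suprathreshold=supra,
    )
    if supra.sum() >= 2:
        slope, _ = np.polyfit(currents[supra], rates[supra], 1)
        fi.slope = float(slope)
    return fi


@dataclass
class ISIStats:
    isis: np.ndarray
    mean: float
    cv: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def isi_stats(spikes: np.ndarray, n_bins: int = 30) -> ISIStats:
    """Inter-spike intervals: mean, coefficient of variation and a
    log-binned histogram (needs >= 2 spikes)."""
    spikes = np.sort(np.asarray(spikes, dtype=float))
    if len(spikes) < 2:
        raise ValueError("need at least two spikes")
    isis = np.diff(spikes)
    mean = float(isis.mean())
    cv = float(isis.std() / mean) if mean > 0 else float("nan")
    lo, hi = isis.min(), isis.max()
    if lo <= 0 or lo == hi:
        edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    else:
        edges = np.geomspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(isis, bins=edges)
    return ISIStats(isis=isis, mean=mean, cv=cv, hist_edges=edges, hist_counts=counts)
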