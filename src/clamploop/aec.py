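"""Active Electrode Compensation (AEC).

Single-electrode current-clamp recordings superimpose the voltage drop
across the pipette on the membrane potential.  AEC identifies a linear,
non-parametric model of the pipette — its lag-indexed impulse response, the
*electrode kernel* — from the response to a uniformly distributed
fluctuating probe current, separates it from the passive membrane
component, and then, online, subtracts the convolution of the injected
current with that kernel from every recorded sample.  Compensation quality
is what makes closed-loop conductance injection through the same pipette
possible: an over-estimated kernel turns the loop into positive feedback
and destabilises it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

from .trace import Trace


@dataclass
class Kernel:
    """Lag-indexed impulse response of a linear system.

    ``taps[k]`` is the voltage (V) produced at lag ``k`` steps by a unit
    current sample (A), i.e. ohms per tap; the recorded response is
    ``U[n] = sum_k taps[k] * I[n-k]``.
    """

    dt: float
    taps: np.ndarray

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.taps.ndim != 1 or len(self.taps) < 1:
            raise ValueError("kernel needs at least one tap")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("kernel taps must be finite")

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    @property
    def R_total(self) -> float:
        """Total (DC) resistance: the sum of the taps."""
        return float(self.taps.sum())

    @property
    def lags(self) -> np.ndarray:
        return self.dt * np.arange(self.n_taps)


def exponential_kernel(R: float, tau: float, dt: float, n_taps: int) -> Kernel:
    """Sampled kernel of a single-exponential (RC) system.

    ``taps[k] = (R*dt/tau) * exp(-k*dt/tau)``; its tap sum approaches R as
    dt/tau -> 0.
    """
    k = np.arange(n_taps)
    return Kernel(dt=dt, taps=(R * dt / tau) * np.exp(-k * dt / tau))


# ---------------------------------------------------------------------------
# probe and estimation
# ---------------------------------------------------------------------------


def generate_probe_current(
    amplitude: float, duration: float, dt: float, seed: int = 0
) -> Trace:
    """I.i.d. uniform probe current over the symmetric range [-amplitude, amplitude].

    Zero mean by construction of the range; deterministic for a given seed.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    return Trace(dt=dt, values=rng.uniform(-amplitude, amplitude, size=n), unit="A")


def estimate_full_kernel(
    I_probe: Trace,
    V_rec: Trace,
    n_taps: int,
    ridge: float = 0.0,
) -> Kernel:
    """Least-squares estimate of the combined electrode+membrane kernel.

    Solves ``V_rec[n] ~ mean(V) + sum_k taps[k] * I_probe[n-k]`` over all
    samples with a full lag history, optionally ridge-regularised.  The
    normal equations are accumulated in blocks so arbitrarily long probes
    fit in memory.
    """
    if not math.isclose(I_probe.dt, V_rec.dt):
        raise ValueError("probe and recording must share dt")
    N = min(len(I_probe), len(V_rec))
    if N < 4 * n_taps:
        raise ValueError("need a probe much longer than the kernel")
    I = I_probe.values[:N]
    V = V_rec.values[:N]

    # rows n = n_taps-1 .. N-1 of the design matrix [I[n], ..., I[n-K+1], 1];
    # the explicit intercept column absorbs the resting potential
    win = sliding_window_view(I, n_taps)[:, ::-1]  # (N-K+1, K) view
    y = V[n_taps - 1 :]
    m = n_taps + 1
    A = np.zeros((m, m))
    b = np.zeros(m)
    block = 16384
    for i in range(0, win.shape[0], block):
        X = np.empty((min(block, win.shape[0] - i), m))
        X[:, :n_taps] = win[i : i + block]
        X[:, n_taps] = 1.0
        A += X.T @ X
        b += X.T @ y[i : i + block]
    if ridge > 0.0:
        idx = np.arange(n_taps)
        A[idx, idx] += ridge * win.shape[0]
    # equilibrate for the cond check: current columns are ~1e-10 A against
    # the unit intercept column
    scale = np.sqrt(np.diag(A))
    scale[scale == 0.0] = 1.0
    As = A / np.outer(scale, scale)
    if not np.all(np.isfinite(As)) or np.linalg.cond(As) > 1e10:
        raise np.linalg.LinAlgError(
            "rank-deficient probe (e.g. constant current); use a fluctuating probe"
        )
    sol = np.linalg.solve(As, b / scale) / scale
    return Kernel(dt=I_probe.dt, taps=sol[:n_taps])


def _exp_model(t, amp, tau):
    return amp * np.exp(-t / tau)


def split_electrode_kernel(
    K_full: Kernel,
    membrane_tail_start: float,
) -> tuple[Kernel, float, float]:
    """Separate the electrode kernel from the passive membrane component.

    The tail of the full kernel beyond ``membrane_tail_start`` (chosen past
    the electrode's time scale) is fitted with a single exponential, giving
    the membrane resistance ``R_m`` and time constant ``tau_m``.  The
    electrode kernel is then recovered with the Fourier-domain correction
    for the membrane's filtering of electrode-passed current,

        K_e(f) = K(f) / (1 + K_m(f) / R_e),

    iterating on the electrode resistance ``R_e = sum(K_e)``.

    Returns ``(K_electrode, R_m, tau_m)``.  A non-decaying tail raises with
    advice to use a longer probe or a later tail start.
    """
    dt = K_full.dt
    k0 = int(round(membrane_tail_start / dt))
    if k0 < 1 or k0 >= K_full.n_taps - 4:
        raise ValueError("membrane_tail_start must fall inside the kernel")
    t_tail = K_full.lags[k0:]
    y_tail = K_full.taps[k0:]

    peak = float(np.max(np.abs(K_full.taps)))
    if float(np.max(np.abs(y_tail))) < 1e-6 * peak:
        # electrode-only kernel: nothing to remove
        return Kernel(dt=dt, taps=K_full.taps.copy()), 0.0, 0.0

    # initial guess from a log-linear fit on the positive part of the tail
    pos = y_tail > 0
    if pos.sum() < 4:
        raise ValueError(
            "kernel tail is not a decaying exponential; use a longer probe or a "
            "later membrane_tail_start"
        )
    slope, intercept = np.polyfit(t_tail[pos], np.log(y_tail[pos]), 1)
    if slope >= 0:
        raise ValueError(
            "kernel tail does not decay; use a longer probe or a later "
            "membrane_tail_start"
        )
    tau0 = -1.0 / slope
    amp0 = math.exp(intercept)
    try:
        (amp, tau_m), _ = curve_fit(
            _exp_model, t_tail, y_tail, p0=(amp0, tau0), maxfev=10000
        )
    except RuntimeError as e:  # pragma: no cover - scipy failure path
        raise ValueError(
            "exponential fit of the kernel tail failed; use a longer probe or a "
            "later membrane_tail_start"
        ) from e
    if tau_m <= 0 or amp <= 0:
        raise ValueError("kernel tail fit gave a non-decaying membrane component")
    # amp = R_m*dt/tau_m for the sampled exponential kernel
    R_m = amp * tau_m / dt

    K_m = _exp_model(K_full.lags, amp, tau_m)
    nfft = 4 * K_full.n_taps
    K_hat = np.fft.rfft(K_full.taps, nfft)
    Km_hat = np.fft.rfft(K_m, nfft)
    # initial electrode resistance from plain subtraction over the window
    # (consistent truncation of the membrane tail)
    taps_e = K_full.taps - K_m
    R_e = max(float(taps_e.sum()), 1e-3 * abs(K_full.R_total))
    for _ in range(8):
        Ke_hat = K_hat / (1.0 + Km_hat / R_e)
        taps_e = np.fft.irfft(Ke_hat, nfft)[: K_full.n_taps]
        R_new = float(taps_e.sum())
        if R_new <= 0:
            raise ValueError("electrode/membrane separation failed (R_e <= 0)")
        if abs(R_new - R_e) < 1e-9 * abs(R_e):
            R_e = R_new
            break
        R_e = R_new
    return Kernel(dt=dt, taps=taps_e), float(R_m), float(tau_m)


# ---------------------------------------------------------------------------
# online compensation
# ---------------------------------------------------------------------------


@dataclass
class AECState:
    """Online compensator: electrode kernel plus the injected-current history.

    ``history[0]`` is the newest current sample.  When ``enabled`` is False
    the recorded voltage passes through unchanged (the history is still
    updated so compensation can be switched on seamlessly).
    """

    electrode_kernel: Kernel
    enabled: bool = True
    history: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.history is None:
            self.history = np.zeros(self.electrode_kernel.n_taps)
        if len(self.history) != self.electrode_kernel.n_taps:
            raise ValueError("history length must equal the kernel length")


def compensate_online(
    state: AECState, V_rec_sample: float, I_injected_sample: float
) -> float:
    """Push one current sample and return the compensated potential.

    ``V_membrane_estimate = V_rec - sum_k taps[k] * I[n-k]``; returns the
    raw sample unchanged while disabled.
    """
    h = state.history
    h[1:] = h[:-1]
    h[0] = I_injected_sample
    if not state.enabled:
        return V_rec_sample
    return V_rec_sample - float(np.dot(state.electrode_kernel.taps, h))


def compensate_trace(kernel: Kernel, V_rec: Trace, I: Trace, enabled: bool = True) -> Trace:
    """Offline convenience: compensate a whole recording at once."""
    if not math.isclose(V_rec.dt, I.dt):
        raise ValueError("voltage and current traces must share dt")
    if not enabled:
        return V_rec.copy()
    art = np.convolve(I.values, kernel.taps)[: len(V_rec)]
    return Trace(dt=V_rec.dt, values=V_rec.values - art, unit="V", t0=V_rec.t0)


# ---------------------------------------------------------------------------
# kernel files
# ---------------------------------------------------------------------------


def write_kernel_file(path, kernel: Kernel) -> None:
    data = np.column_stack([kernel.lags, kernel.taps])
    np.savetxt(path, data, header=f"dt={kernel.dt!r}  columns: lag_s tap_ohm", comments="# ")


def read_kernel_file(path) -> Kernel:
    dt = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "dt=" in line:
                dt = float(line.split("dt=")[1].split()[0])
            if not line.startswith("#"):
                break
    data = np.loadtxt(path)
    if dt is None:
        dt = float(data[1, 0] - data[0, 0])
    return Kernel(dt=dt, taps=data[:, 1])
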