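"""Phase locking of two weakly, symmetrically, delay-coupled circuits.

With each circuit oscillating on the same limit cycle and cross-coupling
``eps G_s A_other(t - d)`` entering the synaptic equation, the phase lag
``theta`` between the circuits obeys ``dtheta/dt = G(theta)`` with

    H(theta) = (eps G_s / T) * int_0^T Z_I(s) A(s - theta) ds
    G(theta) = H(theta - d) - H(-theta - d)

Zeros of G are steady phase lags; a negative slope at the crossing means the
lag is stable.  ``theta`` and ``d`` are carried in the cycle's time units
(ms); conversions to radians use ``2 pi / T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import SimResult, simulate_coupled
from .prc import PRCCurve, smoothed_peaks

__all__ = [
    "CouplingSpec",
    "FixedPoint",
    "PhaseInteraction",
    "interaction_H",
    "g_function",
    "delay_bifurcation",
    "empirical_phase_lag",
    "circular_distance",
    "simulate_coupled",
]


@dataclass
class CouplingSpec:
    """Cross-circuit coupling: strength ``eps * G_s`` (mV ms) and delay d (ms).

    Only the product ``eps * G_s`` enters every formula, so ``eps`` is pure
    bookkeeping for the weak-coupling assumption."""

    G_s: float = 0.2
    eps: float = 1.0
    d: float = 0.5

    def strength(self) -> float:
        return self.eps * self.G_s

    def check_weak(self, J_s: float) -> None:
        if self.strength() > 0.2 * J_s:
            warnings.warn(
                f"eps*G_s = {self.strength():.3g} is not small against "
                f"J_s = {J_s:.3g}; the weak-coupling reduction may not apply",
                stacklevel=2,
            )


@dataclass
class FixedPoint:
    theta_ms: float
    theta_rad: float
    stable: bool
    slope: float  # dG/dtheta at the zero (1/ms per ms)
    merged: bool = False  # zeros closer than 2 grid steps were merged


@dataclass
class PhaseInteraction:
    """H and G on the cycle's periodic time grid, with classified zeros."""

    t_grid: np.ndarray  # ms, M uniform samples of [0, T)
    T: float
    H: np.ndarray
    G: np.ndarray
    d: float
    fixed_points: list[FixedPoint] = field(default_factory=list)

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * self.t_grid / self.T

    def stable_lags(self) -> list[FixedPoint]:
        return [fp for fp in self.fixed_points if fp.stable]


def interaction_H(
    Z_I: np.ndarray | PRCCurve,
    A: np.ndarray,
    T: float,
    coupling_strength: float,
) -> np.ndarray:
    """``H(theta) = (eps G_s / T) * circular-correlation(Z_I, A)``.

    ``Z_I`` and ``A`` must be sampled on the same uniform periodic grid of
    one period (``Z_I`` may be a :class:`PRCCurve`, in which case it is
    resampled onto the grid of ``A``).  The periodic integral is the exact
    trapezoid sum on the circle (endpoint weights wrap), evaluated by FFT.
    """
    A = np.asarray(A, dtype=float)
    M = len(A)
    if isinstance(Z_I, PRCCurve):
        Z = Z_I(2.0 * np.pi * np.arange(M) / M)
    else:
        Z = np.asarray(Z_I, dtype=float)
        if len(Z) != M:
            raise ValueError(
                f"grid mismatch: len(Z_I)={len(Z)} vs len(A)={M}; "
                "resample one onto the other"
            )
    # sum_m Z[m] A[(m - k) mod M] for every shift k
    corr = np.fft.irfft(np.fft.rfft(Z) * np.conj(np.fft.rfft(A)), n=M)
    return coupling_strength * corr / M


def _periodic_interp(t_grid: np.ndarray, T: float, values: np.ndarray):
    xp = np.concatenate([t_grid, [t_grid[0] + T]])
    fp = np.concatenate([values, [values[0]]])

    def f(t):
        return np.interp(np.mod(t, T), xp, fp)

    return f


def g_function(
    H: np.ndarray,
    T: float,
    d: float,
    coupling_check: tuple[float, float] | None = None,
) -> PhaseInteraction:
    """Build ``G(theta) = H(theta - d) - H(-theta - d)`` and classify zeros.

    Zeros are located by sign change plus linear interpolation; stability is
    the sign of the interpolated slope (negative = stable).  Zeros closer
    than two grid steps are merged and flagged.
    """
    H = np.asarray(H, dtype=float)
    M = len(H)
    t = T * np.arange(M) / M
    Hf = _periodic_interp(t, T, H)
    G = Hf(t - d) - Hf(-t - d)
    dts = T / M
    fps: list[FixedPoint] = []
    Gw = np.concatenate([G, [G[0]]])
    for i in range(M):
        a, b = Gw[i], Gw[i + 1]
        if a == 0.0 and b != 0.0:
            z, slope = t[i], (b - a) / dts
        elif a * b < 0.0:
            z = t[i] + dts * a / (a - b)
            slope = (b - a) / dts
        else:
            continue
        fps.append(
            FixedPoint(
                theta_ms=float(np.mod(z, T)),
                theta_rad=float(2 * np.pi * np.mod(z, T) / T),
                stable=slope < 0,
                slope=float(slope),
            )
        )
    # merge zeros closer than 2 grid steps (circularly)
    merged: list[FixedPoint] = []
    for fp in sorted(fps, key=lambda f: f.theta_ms):
        if merged:
            gap = fp.theta_ms - merged[-1].theta_ms
            if gap < 2 * dts:
                merged[-1].merged = True
                continue
        merged.append(fp)
    if len(merged) > 1:
        wrap_gap = (merged[0].theta_ms + T) - merged[-1].theta_ms
        if wrap_gap < 2 * dts:
            merged[0].merged = True
            merged.pop()
    return PhaseInteraction(t_grid=t, T=T, H=H, G=G, d=d, fixed_points=merged)


def delay_bifurcation(
    H: np.ndarray, T: float, d_values: np.ndarray
) -> list[PhaseInteraction]:
    """Sweep the conduction delay and collect the locking diagram (zeros of
    G with stability for each d)."""
    return [g_function(H, T, float(d)) for d in np.atleast_1d(d_values)]


def empirical_phase_lag(
    res1: SimResult,
    res2: SimResult,
    T: float,
    discard_fraction: float = 0.5,
) -> tuple[float, float]:
    """Observed lag (ms, in [0, T)) between two simulated circuits.

    Peak times of the smoothed activities are matched nearest-neighbor over
    the last ``1 - discard_fraction`` of the run; the result is the circular
    mean of the per-peak differences with its circular SD.
    """
    t_start = res1.t[-1] * discard_fraction
    p1 = smoothed_peaks(res1.t, res1.A, T)
    p2 = smoothed_peaks(res2.t, res2.A, T)
    p1 = p1[p1 > t_start]
    p2 = p2[p2 > t_start]
    if len(p1) < 3 or len(p2) < 3:
        raise RuntimeError("too few activity peaks to estimate a phase lag")
    diffs = []
    for tp in p1:
        j = np.argmin(np.abs(p2 - tp))
        diffs.append(tp - p2[j])
    ang = 2.0 * np.pi * np.asarray(diffs) / T
    zbar = np.mean(np.exp(1j * ang))
    lag = np.mod(np.angle(zbar), 2.0 * np.pi) * T / (2.0 * np.pi)
    R = np.abs(zbar)
    circ_sd = np.sqrt(max(-2.0 * np.log(max(R, 1e-12)), 0.0)) * T / (2.0 * np.pi)
    return float(lag), float(circ_sd)


def circular_distance(a_ms: float, b_ms: float, T: float) -> float:
    """Shortest distance between two lags on the period circle (ms)."""
    d = np.mod(a_ms - b_ms, T)
    return float(min(d, T - d))
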