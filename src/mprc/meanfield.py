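"""Refractory-density (age-structured) mean-field solver.

The density ``q(t, r)`` of neuron ages obeys the transport equation

    dq/dt + dq/dr = -S(h(t), r) q,      q(t, 0) = A(t) = int S q dr,

with input ``h = I_ext + I_s`` and exponential synapse
``tau_s dI_s/dt = -I_s + J_s A``.  Integration is by first-order
characteristics on a uniform grid with ``dr = dt``: each step shifts the
density one cell toward larger ages with survival factor ``1 - dt S`` and
re-injects the fired mass as the newborn boundary cell, so the discrete
(cell-sum) mass is conserved exactly up to the truncation leak past
``r_max``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hazards import HazardModel, rate_for_quadrature

__all__ = [
    "DensityState",
    "SteadyState",
    "LimitCycle",
    "MeanFieldSolver",
    "SquarePulse",
    "default_r_max",
    "gaussian_initial_state",
    "steady_state",
    "find_limit_cycle",
    "NoOscillationError",
]


class NoOscillationError(RuntimeError):
    """Raised when no limit cycle can be detected (asynchronous regime)."""


def default_r_max(hazard: HazardModel, h: float, factor: float = 1.25) -> float:
    """Age-grid truncation: ``1.25 T_ref`` when a refractory time exists,
    otherwise the age where the survivor function at input ``h`` drops
    below 1e-9."""
    if hazard.t_ref > 0:
        return factor * hazard.t_ref
    # no refractory period: walk out until the cumulative hazard is large
    r, dr, cum = 0.0, 0.05, 0.0
    while cum < 21.0 and r < 1e4:  # exp(-21) ~ 7.6e-10
        r += dr
        cum += dr * float(np.mean(hazard.rate(h, np.array([r - dr, r]))))
    return r


@dataclass
class DensityState:
    """Mean-field state: age density on the grid plus the synaptic current."""

    r_grid: np.ndarray
    q: np.ndarray
    I_s: float = 0.0
    t: float = 0.0
    leaked: float = 0.0  # cumulative mass that reached r_max (recycled)

    def mass(self) -> float:
        """Cell-sum (finite-volume) mass ``dt * sum q`` — the quantity the
        scheme conserves exactly."""
        dr = self.r_grid[1] - self.r_grid[0]
        return float(np.sum(self.q) * dr)

    def copy(self) -> "DensityState":
        return copy.deepcopy(self)


@dataclass
class SteadyState:
    """Asynchronous (time-independent) solution."""

    A_inf: float
    h_inf: float
    r_grid: np.ndarray
    q_inf: np.ndarray
    residual: float = 0.0


@dataclass
class LimitCycle:
    """One period of the oscillatory mean-field solution.

    Sample ``m`` is phase ``theta = 2 pi m / M``; phase 0 is anchored at the
    upward crossing of ``I_s`` through its cycle mean (the Poincare section).
    """

    T: float
    r_grid: np.ndarray
    q: np.ndarray  # (M, J) snapshots
    I_s: np.ndarray  # (M,)
    A: np.ndarray  # (M,) activity = q[:, 0]
    dt: float  # sample spacing T / M (~ the solver step)
    periodicity_error: float = 0.0  # relative ||state(0) - state(T)||

    @property
    def M(self) -> int:
        return len(self.I_s)

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.M) / self.M

    def state_at(self, m: int) -> DensityState:
        m = int(m) % self.M
        return DensityState(self.r_grid, self.q[m].copy(), float(self.I_s[m]), t=0.0)

    def save(self, path) -> None:
        np.savez(
            path,
            T=self.T,
            r_grid=self.r_grid,
            q=self.q,
            I_s=self.I_s,
            A=self.A,
            dt=self.dt,
            periodicity_error=self.periodicity_error,
        )

    @classmethod
    def load(cls, path) -> "LimitCycle":
        z = np.load(path)
        return cls(
            T=float(z["T"]),
            r_grid=z["r_grid"],
            q=z["q"],
            I_s=z["I_s"],
            A=z["A"],
            dt=float(z["dt"]),
            periodicity_error=float(z["periodicity_error"]),
        )


@dataclass
class SquarePulse:
    """Additive square perturbation: ``route='external'`` adds to ``I_ext``
    (enters ``h`` directly), ``route='synaptic'`` adds to the drive of the
    ``tau_s dI_s/dt`` equation (enters ``h`` through the synaptic filter,
    the pathway the mPRC ``Z_Is`` measures)."""

    onset: float
    duration: float
    amplitude: float
    route: str = "synaptic"

    def __post_init__(self):
        if self.route not in ("synaptic", "external"):
            raise ValueError(f"unknown pulse route {self.route!r}")

    def value(self, t: float) -> float:
        return self.amplitude if self.onset <= t < self.onset + self.duration else 0.0


def gaussian_initial_state(
    hazard: HazardModel,
    dt: float,
    r_max: float | None = None,
    mean: float | None = None,
    std: float | None = None,
    I_s: float = 0.0,
    h_ref: float = 0.0,
) -> DensityState:
    """Normalized Gaussian age profile (default mean ``T_ref/2``, std
    ``T_ref/6``), truncated at 0 — the initialization used for both the
    network and the mean-field runs."""
    if r_max is None:
        r_max = default_r_max(hazard, h_ref)
    r = np.arange(0.0, r_max + 0.5 * dt, dt)
    t_ref = hazard.t_ref if hazard.t_ref > 0 else r_max / 2.0
    mean = t_ref / 2.0 if mean is None else mean
    std = t_ref / 6.0 if std is None else std
    q = np.exp(-0.5 * ((r - mean) / std) ** 2)
    q /= q.sum() * dt
    return DensityState(r, q, I_s=I_s, t=0.0)


class MeanFieldSolver:
    """Characteristics integrator for the refractory-density equation.

    Parameters
    ----------
    hazard : the escape-rate model.
    I_ext : external current, a scalar or a callable of time (mV).
    J_s : recurrent synaptic efficiency (mV ms).
    tau_s : synaptic decay (ms).
    dt : step, which is also the age-grid spacing (ms).
    decay : per-step survival factor; ``"linear"`` is the first-order
        ``1 - dt S`` (requires ``dt S < 1``), ``"exp"`` is ``exp(-dt S)``
        (unconditionally stable, same first order).
    """

    def __init__(
        self,
        hazard: HazardModel,
        I_ext,
        J_s: float,
        tau_s: float,
        dt: float,
        r_max: float | None = None,
        decay: str = "linear",
    ):
        if dt <= 0 or tau_s <= 0:
            raise ValueError("dt and tau_s must be positive")
        if decay not in ("linear", "exp"):
            raise ValueError(f"unknown decay mode {decay!r}")
        self.hazard = hazard
        self.I_ext = I_ext if callable(I_ext) else (lambda t, v=float(I_ext): v)
        self.J_s = float(J_s)
        self.tau_s = float(tau_s)
        self.dt = float(dt)
        if r_max is None:
            r_max = default_r_max(hazard, self.I_ext(0.0))
        self.r_grid = np.arange(0.0, r_max + 0.5 * dt, dt)
        self.decay = decay
        self._shape = hazard.shape(self.r_grid) if hazard.separable else None

    def new_state(self, q=None, I_s: float = 0.0) -> DensityState:
        if q is None:
            st = gaussian_initial_state(
                self.hazard, self.dt, r_max=self.r_grid[-1], I_s=I_s
            )
            st.r_grid = self.r_grid
            return st
        return DensityState(self.r_grid, np.asarray(q, float).copy(), I_s, 0.0)

    def _rate(self, h: float) -> np.ndarray:
        if self._shape is not None:
            return np.exp(h) * self._shape
        return self.hazard.rate(h, self.r_grid)

    def activity(self, state: DensityState, pulse: SquarePulse | None = None) -> float:
        h = self._h(state, pulse)
        return float(np.sum(self._rate(h) * state.q) * self.dt)

    def _h(self, state: DensityState, pulse: SquarePulse | None) -> float:
        h = self.I_ext(state.t) + state.I_s
        if pulse is not None and pulse.route == "external":
            h += pulse.value(state.t)
        return h

    def step(self, state: DensityState, pulse: SquarePulse | None = None) -> float:
        """Advance one step in place; returns the new boundary activity.

        Order per step: fired mass ``dt sum S q`` becomes the newborn cell,
        survivors shift one cell toward larger ages, the synapse integrates
        the pre-step activity, and the leak past ``r_max`` is accumulated.
        """
        dt = self.dt
        q = state.q
        h = self._h(state, pulse)
        S = self._rate(h)
        if self.decay == "linear":
            # survival factor clamped at 0: cells with S dt >= 1 (only ever
            # the essentially empty deep-tail cells) fire entirely in-step
            surv = np.maximum(1.0 - S * dt, 0.0)
        else:
            surv = np.exp(-S * dt)
        fired = float(np.sum((1.0 - surv) * q))  # newborn rate = activity
        # survivors reaching r_max are cycled through the boundary (the grid
        # is truncated where the whole population has fired); logged as leak
        top = q[-1] * surv[-1]
        state.leaked += top * dt
        fired += top
        q[1:] = q[:-1] * surv[:-1]
        q[0] = fired
        drive = self.J_s * fired
        if pulse is not None and pulse.route == "synaptic":
            drive += pulse.value(state.t)
        state.I_s += dt * (-state.I_s + drive) / self.tau_s
        state.t += dt
        return fired

    def run(
        self,
        state: DensityState,
        duration: float,
        pulse: SquarePulse | None = None,
        record_q: bool = False,
    ):
        """Integrate for ``duration`` ms (in place).

        Returns ``(t, A, I_s)`` series sampled after each step, plus the
        ``(n_steps, J)`` matrix of density snapshots when ``record_q``.
        """
        n = int(round(duration / self.dt))
        t = np.empty(n)
        A = np.empty(n)
        Is = np.empty(n)
        Q = np.empty((n, len(self.r_grid))) if record_q else None
        for i in range(n):
            A[i] = self.step(state, pulse)
            t[i] = state.t
            Is[i] = state.I_s
            if record_q:
                Q[i] = state.q
        if record_q:
            return t, A, Is, Q
        return t, A, Is


def steady_state(
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    r_max: float | None = None,
    dr: float = 1e-3,
    tol: float = 1e-13,
) -> SteadyState:
    """Asynchronous steady state ``A_inf^-1 = int exp(-int_0^r S(h_inf,s) ds) dr``
    with ``h_inf = I_ext + J_s A_inf``.

    Solved by a bracketed root find on the residual ``A * I(h(A)) - 1``
    (the mean ISI at fixed input times the rate must be one).  For the pure
    Heaviside hazard (``exp_relax`` with ``tau = 0``) the quadrature reduces
    to the closed form ``A_inf = (T_ref + exp(-h_inf))^-1``, which is used
    directly; the returned ``residual`` is the closed form's own residual in
    that case and the quadrature residual otherwise.
    """
    if r_max is None:
        r_max = default_r_max(hazard, I_ext + J_s / max(hazard.t_ref, 1.0))
    closed = getattr(hazard, "form_id", "") == "exp_relax" and hazard.tau == 0.0

    if closed:
        t_ref = hazard.t_ref

        def resid(A):
            return A * (t_ref + np.exp(-(I_ext + J_s * A))) - 1.0

    else:
        r = np.arange(0.0, r_max + 0.5 * dr, dr)

        def mean_isi(h):
            S = hazard.rate(h, r)
            cum = np.concatenate([[0.0], np.cumsum(0.5 * (S[1:] + S[:-1]) * dr)])
            return float(np.trapezoid(np.exp(-cum), r))

        def resid(A):
            return A * mean_isi(I_ext + J_s * A) - 1.0

    hi = 1.5 / max(hazard.t_ref, 1e-2)
    while resid(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("steady_state: failed to bracket a root")
    A_inf = brentq(resid, 1e-12, hi, xtol=tol, rtol=8.9e-16)
    h_inf = I_ext + J_s * A_inf
    grid = np.arange(0.0, r_max + 0.5 * dr, dr)
    S, _ = rate_for_quadrature(hazard, h_inf, grid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (S[1:] + S[:-1]) * dr)])
    q_inf = A_inf * np.exp(-cum)
    return SteadyState(
        A_inf=float(A_inf),
        h_inf=float(h_inf),
        r_grid=grid,
        q_inf=q_inf,
        residual=float(resid(A_inf)),
    )


def _upward_crossings(t: np.ndarray, x: np.ndarray, level: float) -> np.ndarray:
    """Sub-step upward crossing times of ``x`` through ``level`` by linear
    interpolation."""
    below = x[:-1] < level
    above = x[1:] >= level
    idx = np.nonzero(below & above)[0]
    frac = (level - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def find_limit_cycle(
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    tau_s: float,
    dt: float,
    r_max: float | None = None,
    t_transient: float = 800.0,
    t_measure: float = 400.0,
    cycle_tol: float = 5e-3,
    n_periods_avg: int = 10,
    decay: str = "linear",
    osc_threshold: float = 1e-3,
) -> LimitCycle:
    """Integrate past the transient and extract one period of the oscillation.

    The period is the mean interval between upward crossings of ``I_s``
    through its mean over the last ``n_periods_avg`` estimated periods; the
    stored cycle starts at a crossing (phase 0) and is resampled onto
    ``M = round(T/dt)`` uniform samples by linear interpolation in time.

    Raises
    ------
    NoOscillationError
        if ``I_s`` never crosses its mean (asynchronous regime) or if the
        crossing intervals drift by more than ``cycle_tol`` relative.
    """
    solver = MeanFieldSolver(hazard, I_ext, J_s, tau_s, dt, r_max=r_max, decay=decay)
    state = solver.new_state()
    solver.run(state, t_transient)
    anchor = state.copy()
    t, A, Is = solver.run(state, t_measure)
    level = float(np.mean(Is[len(Is) // 2 :]))
    # an oscillation must ride well above the numerical ripple of a decayed
    # transient; the floor is relative to the standing current scale
    if np.ptp(Is[len(Is) // 2 :]) < osc_threshold * (abs(level) + 0.1):
        raise NoOscillationError(
            "no oscillation detected: I_s is flat in the measurement window"
        )
    crossings = _upward_crossings(t, Is, level)
    if len(crossings) < max(4, n_periods_avg // 2):
        raise NoOscillationError(
            f"no oscillation detected: {len(crossings)} crossings of the mean "
            f"I_s level in {t_measure} ms"
        )
    intervals = np.diff(crossings)[-n_periods_avg:]
    T = float(np.mean(intervals))
    drift = float(np.std(intervals) / T)
    if drift > cycle_tol:
        raise NoOscillationError(
            f"period drift {drift:.2e} exceeds cycle_tol={cycle_tol:.1e}; "
            "increase t_transient"
        )
    # re-run from the anchor up to a late crossing, then record one period
    t_cross = crossings[-3] if len(crossings) >= 3 else crossings[0]
    n_skip = int(np.floor((t_cross - anchor.t) / dt))
    offset = t_cross - (anchor.t + n_skip * dt)  # in [0, dt)
    state = anchor
    if n_skip > 0:
        solver.run(state, n_skip * dt)
    M = int(round(T / dt))
    n_rec = M + 3
    _, A_rec, Is_rec, Q_rec = solver.run(state, n_rec * dt, record_q=True)
    # resample onto M uniform samples spanning exactly [t_cross, t_cross + T)
    dts = T / M
    pos = (offset + dts * np.arange(M)) / dt  # fractional step index
    i0 = np.floor(pos).astype(int)
    w = pos - i0
    q_cycle = (1 - w)[:, None] * Q_rec[i0] + w[:, None] * Q_rec[i0 + 1]
    Is_cycle = (1 - w) * Is_rec[i0] + w * Is_rec[i0 + 1]
    A_cycle = (1 - w) * A_rec[i0] + w * A_rec[i0 + 1]
    # periodicity check: state one period after the cycle start vs sample 0
    posT = (offset + T) / dt
    iT = int(np.floor(posT))
    wT = posT - iT
    qT = (1 - wT) * Q_rec[iT] + wT * Q_rec[iT + 1]
    IsT = (1 - wT) * Is_rec[iT] + wT * Is_rec[iT + 1]
    num = np.sqrt(np.sum((qT - q_cycle[0]) ** 2) * dt + (IsT - Is_cycle[0]) ** 2)
    den = np.sqrt(np.sum(q_cycle[0] ** 2) * dt + Is_cycle[0] ** 2)
    return LimitCycle(
        T=T,
        r_grid=solver.r_grid,
        q=q_cycle,
        I_s=Is_cycle,
        A=A_cycle,
        dt=dts,
        periodicity_error=float(num / den),
    )
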