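"""Backward adjoint solver: the macroscopic phase-resetting curve.

Around a stable limit cycle ``(q_bar(t,r), I_bar_s(t))`` of period ``T`` the
adjoint pair ``(Z_q(t,r), Z_Is(t))`` solves

    -dZ_q/dt - dZ_q/dr = -S(h,r) [Z_q - Z_q(t,0) - (J_s/tau_s) Z_Is]
    -dZ_Is/dt = -Z_Is/tau_s
                - int [Z_q - Z_q(t,0) - (J_s/tau_s) Z_Is] dS/dh q_bar dr

subject to the normalization

    int Z_q d_t q_bar dr + Z_Is dI_bar_s/dt = 2 pi / T.

``Z_Is`` is the macroscopic PRC: the asymptotic phase shift (radians) per mV
of instantaneous displacement of the synaptic current.  The system is
unstable forward in time, so it is integrated backward along characteristics
over the periodic cycle coefficients until successive periods agree; the
backward flow contracts every mode except the phase mode, whose scale (and
sign) the normalization fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hazards import HazardModel
from .meanfield import LimitCycle

__all__ = ["AdjointSolution", "solve_adjoint", "normalize", "mprc", "bilinear_form"]


class AdjointConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


@dataclass
class AdjointSolution:
    """One period of the adjoint; sample ``n`` matches cycle sample ``n``."""

    Z_q: np.ndarray  # (M, J) phase response to density displacement
    Z_Is: np.ndarray  # (M,)  phase response to synaptic-current displacement
    T: float
    r_grid: np.ndarray
    dt: float
    normalized: bool = False
    n_passes: int = 0
    residual: float = np.nan  # sup-norm change over the last backward period
    bracket_deviation: float = np.nan  # max relative dev of the normalization

    @property
    def M(self) -> int:
        return len(self.Z_Is)

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.M) / self.M


def bilinear_form(Z_q, Z_Is, q_p, I_p, dr: float) -> float:
    """Pairing ``int Z_q q_p dr + Z_Is I_p`` (cell-sum quadrature) —
    conserved along linearized trajectories, the defining adjoint property."""
    return float(np.sum(Z_q * q_p) * dr + Z_Is * I_p)


def solve_adjoint(
    cycle: LimitCycle,
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    tau_s: float,
    n_cycles: int = 500,
    adjoint_tol: float = 1e-6,
    extrapolation: str = "copy",
) -> AdjointSolution:
    """Integrate the adjoint system backward over the periodic cycle.

    The terminal condition (``Z_q = 0``, ``Z_Is = 1``) is arbitrary and is
    washed out by the backward contraction; after each full period the
    solution is rescaled to unit sup norm (the phase mode is neutral, so its
    amplitude is meaningless before normalization) and iteration stops when
    the rescaled period changes by less than ``adjoint_tol`` in sup norm.
    The missing top-age node after each backward step is filled by nearest
    -node copy (``extrapolation='copy'``) or two-point linear extrapolation
    (``'linear'``).

    Raises ``AdjointConvergenceError`` (with the residual history) when the
    tolerance is not met in ``n_cycles`` periods — usually a sign the input
    cycle itself is not accurate enough.
    """
    if extrapolation not in ("copy", "linear"):
        raise ValueError(f"unknown extrapolation {extrapolation!r}")
    M = cycle.M
    r = cycle.r_grid
    J = len(r)
    dt = cycle.dt
    dr = r[1] - r[0]
    h_bar = I_ext + cycle.I_s
    sep = hazard.separable
    if sep:
        shape = hazard.shape(r)
        eh = np.exp(h_bar)
    else:
        S_mat = np.empty((M, J))
        dS_mat = np.empty((M, J))
        for n in range(M):
            S_mat[n] = hazard.rate(h_bar[n], r)
            dS_mat[n] = hazard.rate_dh(h_bar[n], r)

    Zq = np.zeros(J)
    Z = 1.0
    Zq_trace = np.zeros((M, J))
    Z_trace = np.zeros(M)
    prev_Zq = None
    prev_Z = None
    history: list[float] = []
    g = J_s / tau_s
    n_passes = 0
    for _ in range(n_cycles):
        n_passes += 1
        for n in range(M - 1, -1, -1):
            if sep:
                S_n = eh[n] * shape
                dS_n = S_n
            else:
                S_n = S_mat[n]
                dS_n = dS_mat[n]
            core = Zq - Zq[0] - g * Z
            intgr = float(np.sum(dS_n * core * cycle.q[n]) * dr)
            Z = Z - dt * (Z / tau_s + intgr)
            Zq[:-1] = Zq[1:] - dt * S_n[1:] * core[1:]
            if extrapolation == "copy":
                Zq[-1] = Zq[-2]
            else:
                Zq[-1] = 2.0 * Zq[-2] - Zq[-3]
            Zq_trace[n] = Zq
            Z_trace[n] = Z
        # gauge fixing: (Z_q = const, Z_Is = 0) is an exact periodic adjoint
        # solution (mass conservation's neutral mode) with zero bracket and
        # zero Z_Is; remove it so the iteration cannot wander along it.
        c = float(np.mean(Zq))
        Zq -= c
        Zq_trace -= c
        scale = np.max(np.abs(Z_trace))
        if scale <= 1e-10 * max(np.max(np.abs(Zq_trace)), 1.0):
            # decoupled (dS/dh = 0) case: the backward flow kills Z_Is and
            # only the trivial Z_Is = 0 is periodic
            return AdjointSolution(
                Zq_trace * 0.0, Z_trace * 0.0, cycle.T, r, dt, False, n_passes, 0.0
            )
        Zq_trace /= scale
        Z_trace /= scale
        Zq = Zq / scale
        Z = Z / scale
        if prev_Z is not None:
            res = max(
                np.max(np.abs(Z_trace - prev_Z)),
                np.max(np.abs(Zq_trace - prev_Zq)),
            )
            history.append(float(res))
            if res < adjoint_tol:
                return AdjointSolution(
                    Zq_trace.copy(),
                    Z_trace.copy(),
                    cycle.T,
                    r,
                    dt,
                    False,
                    n_passes,
                    float(res),
                )
        prev_Zq = Zq_trace.copy()
        prev_Z = Z_trace.copy()
    raise AdjointConvergenceError(
        f"adjoint not converged after {n_cycles} backward periods "
        f"(last residual {history[-1]:.2e}); the limit cycle is probably "
        "not accurate enough — increase t_transient or reduce dt",
        history,
    )


def _cycle_time_derivatives(cycle: LimitCycle):
    """Centered periodic finite differences of the cycle in time."""
    dq = (np.roll(cycle.q, -1, axis=0) - np.roll(cycle.q, 1, axis=0)) / (2 * cycle.dt)
    dIs = (np.roll(cycle.I_s, -1) - np.roll(cycle.I_s, 1)) / (2 * cycle.dt)
    return dq, dIs


def normalization_bracket(adj: AdjointSolution, cycle: LimitCycle) -> np.ndarray:
    """``int Z_q d_t q_bar dr + Z_Is dI_bar_s/dt`` at every cycle sample.

    Constant in time (equal to ``2 pi / T`` once normalized) for an exact
    adjoint; its flatness is the standard quality check.
    """
    dq, dIs = _cycle_time_derivatives(cycle)
    dr = cycle.r_grid[1] - cycle.r_grid[0]
    return np.sum(adj.Z_q * dq, axis=1) * dr + adj.Z_Is * dIs


def normalize(
    adj: AdjointSolution, cycle: LimitCycle, max_deviation: float = 0.10
) -> AdjointSolution:
    """Rescale the adjoint so the bracket equals ``2 pi / T``.

    The rescaling uses the time-mean of the bracket (averaging residual
    scheme error); a sign change or relative deviation beyond
    ``max_deviation`` raises, since then the adjoint (or the cycle feeding
    it) has not converged.  A negative mean flips the overall sign, which
    fixes the phase-advance convention automatically.
    """
    br = normalization_bracket(adj, cycle)
    mean = float(np.mean(br))
    if mean == 0.0 or np.any(np.sign(br) != np.sign(mean)):
        raise RuntimeError(
            "normalization bracket changes sign across the period; "
            "adjoint or cycle insufficiently converged"
        )
    dev = float(np.max(np.abs(br / mean - 1.0)))
    if dev > max_deviation:
        raise RuntimeError(
            f"normalization bracket deviates {dev:.1%} from constancy "
            f"(> {max_deviation:.0%}); adjoint or cycle insufficiently converged"
        )
    scale = (2.0 * np.pi / adj.T) / mean
    return replace(
        adj,
        Z_q=adj.Z_q * scale,
        Z_Is=adj.Z_Is * scale,
        normalized=True,
        bracket_deviation=dev,
    )


def bilinear_drift(
    adj: AdjointSolution,
    cycle: LimitCycle,
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    tau_s: float,
    delta_Is: float = 1e-3,
    n_periods: int = 2,
) -> np.ndarray:
    """Pairing ``<Z(t), dx(t)>`` along a finite-difference forward
    perturbation — the conservation check of the adjoint.

    Two forward trajectories start at cycle sample 0, one displaced by
    ``delta_Is`` in the synaptic current; the pairing of their difference
    with the adjoint is sampled every step over ``n_periods`` periods.  For
    an exact adjoint it is constant in time.
    """
    from .meanfield import MeanFieldSolver

    solver = MeanFieldSolver(
        hazard, I_ext, J_s, tau_s, cycle.dt, r_max=cycle.r_grid[-1]
    )
    ref = cycle.state_at(0)
    pert = cycle.state_at(0)
    pert.I_s += delta_Is
    dr = cycle.r_grid[1] - cycle.r_grid[0]
    M = cycle.M
    n = n_periods * M
    b = np.empty(n)
    for i in range(n):
        solver.step(ref)
        solver.step(pert)
        k = (i + 1) % M
        b[i] = bilinear_form(
            adj.Z_q[k], adj.Z_Is[k], pert.q - ref.q, pert.I_s - ref.I_s, dr
        )
    return b


def mprc(adj: AdjointSolution):
    """The macroscopic PRC: ``Z_Is`` on the cycle's phase axis.

    Phase 0 is the cycle's Poincare anchor (upward mean-crossing of
    ``I_s``); values are in rad/mV of synaptic-current displacement.
    """
    from .prc import PRCCurve

    if not adj.normalized:
        raise ValueError("normalize the adjoint before extracting the mPRC")
    return PRCCurve(theta=adj.theta.copy(), response=adj.Z_Is.copy())
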