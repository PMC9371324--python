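"""Linear stability of the asynchronous state and the Hopf boundary.

Linearizing the refractory-density equation around the steady state
``(A_inf, q_inf)`` gives eigenvalues as roots of a characteristic function
``C(lambda)``.  Two evaluators are provided:

* :func:`characteristic_general` — the quadrature form valid for any hazard,

  ``C(l) = 1 - J k(l) int dS q_inf dr - int S e^{-int_0^r (S+l)} dr
         + J k(l) int S(r) int_0^r dS(x) q_inf(x) e^{-int_x^r (S+l)} dx dr``

  with ``k(l) = 1/(1 + l tau_s)`` the Laplace transform of the synaptic
  filter.

* :func:`characteristic_tau0` — the closed form for the pure Heaviside
  hazard ``exp(h) H(r - T_ref)``:

  ``C0(l) = l - J_s l k(l) A_inf + e^{h_inf} - e^{h_inf - l T_ref}``.

Direct integration shows ``C0(l) = (e^{h_inf} + l) * C(l)`` for that hazard,
so the two share every root except the non-eigenvalue ``l = -e^{h_inf}``;
conservation forces the structural root ``C(0) = 0`` in both.

The Hopf (oscillation-onset) boundary in the ``(I_ext, J_s)`` plane is the
locus ``C0(i omega) = 0`` with ``omega > 0``, traced here by continuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .hazards import HazardModel, rate_for_quadrature
from .meanfield import SteadyState, steady_state

__all__ = [
    "kappa_hat",
    "characteristic_general",
    "characteristic_tau0",
    "complex_roots",
    "max_re_root",
    "hopf_boundary",
    "HopfPoint",
]

#: frequencies below this (1/ms) are treated as the structural lambda=0 root
OMEGA_MIN = 1e-3

_EXP_CAP = 690.0  # keep exponents inside double range


def kappa_hat(lam: complex, tau_s: float) -> complex:
    """Laplace transform of the normalized exponential synaptic filter."""
    return 1.0 / (1.0 + lam * tau_s)


def _require_tau0(hazard: HazardModel) -> None:
    if not (getattr(hazard, "form_id", "") == "exp_relax" and hazard.tau == 0.0):
        raise ValueError(
            "closed-form characteristic requires the exp_relax hazard with tau=0"
        )


def characteristic_general(
    steady: SteadyState,
    hazard: HazardModel,
    J_s: float,
    tau_s: float,
    lam: complex,
) -> complex:
    """Quadrature evaluation of ``C(lambda)`` on the steady-state grid.

    Uses nested trapezoid sums on ``steady.r_grid``; the double integral is
    accumulated in one pass via ``e^{-int_x^r} = e^{-int_0^r} e^{+int_0^x}``.
    Valid for ``Re(lambda)`` not too negative (the integrals must converge on
    the truncated grid).
    """
    r = steady.r_grid
    dr = r[1] - r[0]
    lam = complex(lam)
    S, dS = rate_for_quadrature(hazard, steady.h_inf, r)
    q = steady.q_inf
    cumS = np.concatenate([[0.0], np.cumsum(0.5 * (S[1:] + S[:-1]) * dr)])
    expo = cumS + lam * r
    if np.max(expo.real) > _EXP_CAP:
        # rescale so the largest positive exponent stays representable;
        # the product terms below only ever use differences of expo
        raise RuntimeError(
            "characteristic_general: cumulative hazard too large for the "
            "truncated grid; reduce r_max or use the closed form"
        )
    decay = np.exp(-expo)  # e^{-int_0^r S - lam r}
    grow = np.exp(expo)  # e^{+int_0^x S + lam x}
    k = kappa_hat(lam, tau_s)

    term2 = -J_s * k * np.trapezoid(dS * q, r)
    term3_inner = dS * q * grow
    u = np.concatenate(
        [[0.0], np.cumsum(0.5 * (term3_inner[1:] + term3_inner[:-1]) * dr)]
    )
    term3 = J_s * k * np.trapezoid(S * decay * u, r)
    term4 = -np.trapezoid(S * decay, r)
    return 1.0 + term2 + term3 + term4


def characteristic_tau0(
    steady: SteadyState,
    hazard: HazardModel,
    J_s: float,
    tau_s: float,
    lam: complex,
) -> complex:
    """Closed form for the pure Heaviside hazard (``tau = 0``)."""
    _require_tau0(hazard)
    lam = complex(lam)
    eh = np.exp(steady.h_inf)
    k = kappa_hat(lam, tau_s)
    return lam - J_s * lam * k * steady.A_inf + eh - eh * np.exp(-lam * hazard.t_ref)


def _c0_and_deriv(lam, eh, t_ref, J_s, tau_s, A_inf):
    k = 1.0 / (1.0 + lam * tau_s)
    c = lam - J_s * lam * k * A_inf + eh - eh * np.exp(-lam * t_ref)
    dc = 1.0 - J_s * A_inf * k * k + eh * t_ref * np.exp(-lam * t_ref)
    return c, dc


def complex_roots(
    steady: SteadyState,
    hazard: HazardModel,
    J_s: float,
    tau_s: float,
    sigma_range: tuple[float, float] = (-0.5, 0.5),
    n_sigma: int = 5,
    n_omega: int = 16,
    omega_min: float = OMEGA_MIN,
    tol: float = 1e-11,
) -> np.ndarray:
    """Roots of the tau=0 closed form by damped Newton from a multi-start
    grid in the upper half-plane (roots come in conjugate pairs).  The
    structural root at 0 is excluded.  Heuristic: roots outside the start
    box may be missed."""
    _require_tau0(hazard)
    eh = np.exp(steady.h_inf)
    t_ref, A_inf = hazard.t_ref, steady.A_inf
    omega_max = 3.0 * 2.0 * np.pi / max(t_ref, 1e-6)
    starts = [
        complex(s, w)
        for s in np.linspace(*sigma_range, n_sigma)
        for w in np.linspace(omega_max / n_omega, omega_max, n_omega)
    ]
    roots = []
    for lam in starts:
        for _ in range(80):
            c, dc = _c0_and_deriv(lam, eh, t_ref, J_s, tau_s, A_inf)
            if abs(dc) < 1e-14:
                break
            step = c / dc
            if abs(step) > 2.0:  # damp wild steps
                step *= 2.0 / abs(step)
            lam = lam - step
            if abs(step) < 1e-13:
                break
        c, _ = _c0_and_deriv(lam, eh, t_ref, J_s, tau_s, A_inf)
        if abs(c) < tol and abs(lam.imag) >= omega_min:
            lam = complex(lam.real, abs(lam.imag))
            if not any(abs(lam - z) < 1e-6 for z in roots):
                roots.append(lam)
    return np.array(sorted(roots, key=lambda z: -z.real))


def max_re_root(
    hazard: HazardModel, I_ext: float, J_s: float, tau_s: float
) -> tuple[float, complex | None]:
    """Rightmost non-structural root found by the multi-start search (the
    stability verdict: positive real part means the asynchronous state is
    unstable and an oscillation grows)."""
    ss = steady_state(hazard, I_ext, J_s)
    roots = complex_roots(ss, hazard, J_s, tau_s)
    if len(roots) == 0:
        return -np.inf, None
    return float(roots[0].real), roots[0]


@dataclass
class HopfPoint:
    I_ext: float
    J_s: float
    omega: float


def hopf_boundary(
    I_ext_values: np.ndarray,
    hazard: HazardModel,
    tau_s: float,
    J_scan: tuple[float, float] = (0.5, 80.0),
) -> list[HopfPoint]:
    """Trace the oscillation-onset line ``C0(i omega) = 0`` over ``I_ext``.

    For each ``I_ext`` the pair ``(J_s, omega)`` is solved with the steady
    state updated self-consistently (``h_inf`` depends on ``J_s``); the
    previous point warm-starts the next.  Points where the solver fails or
    leaves ``omega > 0`` are skipped (a gap in the curve).
    """
    _require_tau0(hazard)
    t_ref = hazard.t_ref
    points: list[HopfPoint] = []
    guess = None
    for I_ext in np.atleast_1d(I_ext_values):

        def F(x, I_ext=I_ext):
            J, w = x
            ss = steady_state(hazard, I_ext, J)
            c = characteristic_tau0(ss, hazard, J, tau_s, 1j * w)
            return [c.real, c.imag]

        if guess is None:
            guess = _bracket_hopf(hazard, I_ext, tau_s, J_scan)
            if guess is None:
                continue
        sol = optimize.root(F, guess, method="hybr", tol=1e-12)
        J, w = sol.x
        if not sol.success or w <= OMEGA_MIN or J <= 0:
            refreshed = _bracket_hopf(hazard, I_ext, tau_s, J_scan)
            if refreshed is None:
                guess = None
                continue
            sol = optimize.root(F, refreshed, method="hybr", tol=1e-12)
            J, w = sol.x
            if not sol.success or w <= OMEGA_MIN or J <= 0:
                guess = None
                continue
        points.append(HopfPoint(float(I_ext), float(J), float(w)))
        guess = [J, w]
    return points


def _bracket_hopf(hazard, I_ext, tau_s, J_scan, n: int = 25):
    """Coarse scan in J_s for a sign change of the rightmost root's real
    part; returns a (J, omega) seed or None."""
    Js = np.geomspace(J_scan[0], J_scan[1], n)
    prev = None
    for J in Js:
        re, root = max_re_root(hazard, I_ext, J, tau_s)
        if root is None:
            prev = None
            continue
        if prev is not None and np.sign(re) != np.sign(prev[1]) and prev[1] != 0:
            # linear interpolation in J for the seed
            J0, re0, w0 = prev[0], prev[1], prev[2]
            frac = re0 / (re0 - re)
            return [J0 + frac * (J - J0), w0 + frac * (root.imag - w0)]
        prev = (J, re, root.imag)
    return None
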