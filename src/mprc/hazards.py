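"""Escape-rate (hazard) models for renewal spiking neurons.

A neuron is described by its age ``r`` (time since the last spike) and fires
with instantaneous rate ``S(h, r)`` where ``h`` is the total input (mV).  The
hazard and the interspike-interval (ISI) density are two faces of the same
renewal description::

    ISI(h, r) = S(h, r) * exp(-int_0^r S(h, s) ds)
    S(h, r)   = ISI(h, r) / (1 - int_0^r ISI(h, s) ds)

Units: time in ms, rates in 1/ms, ``h`` in mV entering ``exp(h)`` as a
dimensionless number.  The Heaviside convention is ``H(0) = 1`` so the hazard
switches on exactly at ``r = T_ref``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "HazardModel",
    "ExpRelaxHazard",
    "RampHazard",
    "TanhHazard",
    "TanhCosHazard",
    "GammaISIHazard",
    "TabulatedHazard",
    "ISIDensity",
    "make_preset",
    "hazard_to_isi",
    "isi_to_hazard",
    "dS_dh_from_isi",
    "PRESET_FORMS",
]

PRESET_FORMS = ("exp_relax", "ramp", "tanh", "tanh_cos", "gamma_isi", "tabulated")

#: survivor-function floor below which the hazard quotient is held flat
SURVIVOR_FLOOR = 1e-8


class HazardModel:
    """Base class: an escape rate ``S(h, r)`` and its input derivative.

    Attributes
    ----------
    t_ref : refractory time (ms); ``S = 0`` for ``r < t_ref``.
    tau : threshold-softness time constant (ms) where applicable, else 0.
    separable : True when ``S(h, r) = exp(h) * shape(r)``, enabling fast
        solver paths (then ``dS/dh = S``).
    """

    form_id: str = "base"
    t_ref: float = 0.0
    tau: float = 0.0
    separable: bool = False

    def rate(self, h: float, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def rate_dh(self, h: float, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def shape(self, r: np.ndarray) -> np.ndarray:
        """Age-dependent factor for separable models (``S = exp(h)*shape``)."""
        raise NotImplementedError

    # convenience aliases used throughout the solvers
    def S(self, h, r):
        return self.rate(h, r)

    def dS_dh(self, h, r):
        return self.rate_dh(h, r)


def _check_times(t_ref: float, tau: float) -> None:
    if t_ref < 0:
        raise ValueError(f"negative T_ref: {t_ref}")
    if tau < 0:
        raise ValueError(f"negative tau: {tau}")


@dataclass
class ExpRelaxHazard(HazardModel):
    """``S(h,r) = exp(h) H(r - T_ref) (1 - exp(-(r - T_ref)/tau))``.

    With ``tau = 0`` this degenerates to the pure Heaviside hazard
    ``exp(h) H(r - T_ref)``.
    """

    t_ref: float = 10.0
    tau: float = 5.0
    form_id: str = field(default="exp_relax", init=False)
    separable: bool = field(default=True, init=False)

    def __post_init__(self):
        _check_times(self.t_ref, self.tau)

    def shape(self, r):
        r = np.asarray(r, dtype=float)
        x = r - self.t_ref
        active = x >= 0.0
        if self.tau == 0.0:
            return active.astype(float)
        out = np.zeros_like(r, dtype=float)
        out[active] = -np.expm1(-x[active] / self.tau)
        return out

    def rate(self, h, r):
        return np.exp(h) * self.shape(r)

    def rate_dh(self, h, r):
        return self.rate(h, r)


@dataclass
class RampHazard(HazardModel):
    """Linear-ramp hazard ``S(h,r) = exp(h) H(r - T_ref) eps (r - T_ref)``."""

    t_ref: float = 6.0
    eps: float = 3.0
    form_id: str = field(default="ramp", init=False)
    separable: bool = field(default=True, init=False)

    def __post_init__(self):
        _check_times(self.t_ref, 0.0)
        if self.eps < 0:
            raise ValueError(f"negative ramp slope eps: {self.eps}")

    def shape(self, r):
        r = np.asarray(r, dtype=float)
        x = r - self.t_ref
        return np.where(x >= 0.0, self.eps * x, 0.0)

    def rate(self, h, r):
        return np.exp(h) * self.shape(r)

    def rate_dh(self, h, r):
        return self.rate(h, r)


@dataclass
class TanhHazard(HazardModel):
    """``S(h,r) = exp(h) H(r - T_ref) tanh(exp(h)(r - T_ref))``.

    Not separable: ``h`` also enters through the tanh argument, so
    ``dS/dh = S + exp(2h)(r - T_ref) sech^2(exp(h)(r - T_ref))`` on the
    active side.
    """

    t_ref: float = 5.0
    form_id: str = field(default="tanh", init=False)

    def __post_init__(self):
        _check_times(self.t_ref, 0.0)

    def _active(self, r):
        r = np.asarray(r, dtype=float)
        x = r - self.t_ref
        return x, x >= 0.0

    def rate(self, h, r):
        x, active = self._active(r)
        eh = np.exp(h)
        out = np.zeros_like(x)
        out[active] = eh * np.tanh(eh * x[active])
        return out

    def rate_dh(self, h, r):
        x, active = self._active(r)
        eh = np.exp(h)
        out = np.zeros_like(x)
        xa = x[active]
        th = np.tanh(eh * xa)
        out[active] = eh * th + eh * eh * xa * (1.0 - th * th)
        return out


@dataclass
class TanhCosHazard(HazardModel):
    """``S = exp(h) H(r-T_ref) tanh(exp(h)(r-T_ref)) (1 + eps cos(omega r))``.

    For ``eps > 1`` the printed factor dips below zero at some ages; the rate
    is clamped at 0 there (with ``dS/dh = 0``) to keep the hazard a hazard.
    """

    t_ref: float = 10.0
    eps: float = 3.0
    omega: float = 1.0
    form_id: str = field(default="tanh_cos", init=False)

    def __post_init__(self):
        _check_times(self.t_ref, 0.0)

    def _parts(self, h, r):
        r = np.asarray(r, dtype=float)
        x = r - self.t_ref
        active = x >= 0.0
        eh = np.exp(h)
        mod = 1.0 + self.eps * np.cos(self.omega * r)
        return x, active, eh, mod

    def rate(self, h, r):
        x, active, eh, mod = self._parts(h, r)
        out = np.zeros_like(x)
        out[active] = eh * np.tanh(eh * x[active]) * mod[active]
        return np.maximum(out, 0.0)

    def rate_dh(self, h, r):
        x, active, eh, mod = self._parts(h, r)
        out = np.zeros_like(x)
        xa = x[active]
        th = np.tanh(eh * xa)
        raw = (eh * th + eh * eh * xa * (1.0 - th * th)) * mod[active]
        # derivative vanishes where the clamp is engaged
        raw[eh * th * mod[active] <= 0.0] = 0.0
        out[active] = raw
        return out


@dataclass
class GammaISIHazard(HazardModel):
    """Hazard of the gamma ISI density with shape ``alpha`` and rate ``exp(h)``.

    ``ISI(h,r) = exp(h*alpha)/(alpha-1)! r^(alpha-1) exp(-r exp(h))`` is a
    gamma density; the hazard quotient has the closed derivative
    ``dS/dh = S (alpha - r exp(h)) + r S^2``.  Where the survivor function
    underflows the floor the hazard is held at its last finite value
    (it tends monotonically to ``exp(h)`` anyway).
    """

    alpha: float = 2.0
    form_id: str = field(default="gamma_isi", init=False)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"gamma shape alpha must be positive: {self.alpha}")

    def _quotient(self, h, r):
        r = np.asarray(r, dtype=float)
        lam = np.exp(h)
        x = lam * r
        with np.errstate(divide="ignore", invalid="ignore"):
            # log ISI via log-gamma normalizer; stable for large alpha
            log_isi = (
                self.alpha * h
                + (self.alpha - 1.0) * np.log(np.where(r > 0, r, 1.0))
                - x
                - special.gammaln(self.alpha)
            )
        sf = special.gammaincc(self.alpha, x)
        ok = sf > SURVIVOR_FLOOR
        S = np.zeros_like(r, dtype=float)
        S[ok] = np.exp(log_isi[ok]) / sf[ok]
        if self.alpha < 1.0:
            S[r == 0] = np.inf
        elif self.alpha == 1.0:
            S[r == 0] = lam
        else:
            S[r == 0] = 0.0  # r^(alpha-1) kills the density at age 0
        # hold flat past the survivor floor
        if np.any(~ok) and np.any(ok):
            S[~ok] = S[ok][np.argmax(x[ok])]
        elif np.any(~ok):
            S[~ok] = lam
        return S, x, sf

    def rate(self, h, r):
        S, _, _ = self._quotient(h, r)
        return S

    def rate_dh(self, h, r):
        r = np.asarray(r, dtype=float)
        S, x, sf = self._quotient(h, r)
        ok = sf > SURVIVOR_FLOOR
        out = np.zeros_like(S)
        out[ok] = S[ok] * (self.alpha - x[ok]) + r[ok] * S[ok] ** 2
        # past the floor the hazard is flat in r and saturated in h;
        # d/dh of the asymptote exp(h) is exp(h) ~ S
        out[~ok] = S[~ok]
        return out


@dataclass
class TabulatedHazard(HazardModel):
    """Hazard given on an age grid, e.g. built from a measured ISI density.

    If ``h_scaling`` the table (valid at input level ``h0``) is scaled by
    ``exp(h - h0)``, the prefactor family shared by the analytic presets,
    and then ``dS/dh = S``.  With ``h_scaling=False`` the rate ignores ``h``
    and ``dS/dh = 0``.
    """

    r_grid: np.ndarray = None
    values: np.ndarray = None
    h0: float = 0.0
    h_scaling: bool = True
    t_ref: float = 0.0
    truncation_age: float | None = None
    form_id: str = field(default="tabulated", init=False)

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r_grid.shape != self.values.shape or self.r_grid.ndim != 1:
            raise ValueError("tabulated hazard needs matching 1-d r_grid and values")
        if np.any(self.values < 0):
            raise ValueError("tabulated hazard values must be non-negative")
        # infer the refractory time as the last leading zero
        nz = np.nonzero(self.values > 0)[0]
        if nz.size and nz[0] > 0:
            self.t_ref = float(self.r_grid[nz[0]])

    def _interp(self, r):
        r = np.asarray(r, dtype=float)
        return np.interp(r, self.r_grid, self.values)  # flat beyond the table

    def rate(self, h, r):
        base = self._interp(r)
        if self.h_scaling:
            return base * np.exp(h - self.h0)
        return base

    def rate_dh(self, h, r):
        if self.h_scaling:
            return self.rate(h, r)
        return np.zeros_like(np.asarray(r, dtype=float))


def rate_for_quadrature(model: HazardModel, h: float, r_grid: np.ndarray):
    """``(S, dS/dh)`` on the grid with jump nodes set to the mean of the
    one-sided limits, so trapezoid quadrature of the discontinuous hazard
    (``exp_relax`` with ``tau = 0``) stays second-order accurate."""
    S = model.rate(h, r_grid)
    dS = model.rate_dh(h, r_grid)
    if getattr(model, "form_id", "") == "exp_relax" and model.tau == 0.0:
        k = np.nonzero(np.isclose(r_grid, model.t_ref, rtol=0, atol=1e-12))[0]
        if k.size:
            S = S.copy()
            S[k[0]] *= 0.5  # left limit is 0, right limit exp(h)
            dS = S
    return S, dS


def make_preset(form_id: str, **params) -> HazardModel:
    """Build one of the named hazard presets.

    ``exp_relax(t_ref, tau)``, ``ramp(t_ref, eps)``, ``tanh(t_ref)``,
    ``tanh_cos(t_ref, eps, omega)``, ``gamma_isi(alpha)``,
    ``tabulated(r_grid, values, ...)``.
    """
    forms = {
        "exp_relax": ExpRelaxHazard,
        "ramp": RampHazard,
        "tanh": TanhHazard,
        "tanh_cos": TanhCosHazard,
        "gamma_isi": GammaISIHazard,
        "tabulated": TabulatedHazard,
    }
    if form_id not in forms:
        raise ValueError(f"unknown hazard form {form_id!r}; choose from {PRESET_FORMS}")
    return forms[form_id](**params)


@dataclass
class ISIDensity:
    """Interspike-interval density tabulated on a uniform age grid."""

    r_grid: np.ndarray
    density: np.ndarray
    h: float = 0.0

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.r_grid))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.r_grid, self.density]),
            delimiter=",",
            header="age_ms,density_per_ms",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, h: float = 0.0) -> "ISIDensity":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], h=h)


def hazard_to_isi(model: HazardModel, h: float, r_grid: np.ndarray) -> ISIDensity:
    """ISI density ``S exp(-int_0^r S)`` of a hazard model at input ``h``."""
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid[0] != 0.0:
        raise ValueError("r_grid must start at 0")
    S = model.rate(h, r_grid)
    cum = cumulative_trapezoid(S, r_grid, initial=0.0)
    return ISIDensity(r_grid, S * np.exp(-cum), h=h)


def _survivor(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Survivor function ``1 - int_0^r ISI`` evaluated as the backward tail
    integral ``surv(r_max) + int_r^{r_max} ISI``, so the relative quadrature
    error stays O(dr^2) even deep in the tail where the forward form cancels
    catastrophically (the known fragility of the hazard quotient).

    The beyond-grid mass ``surv(r_max)`` cannot be read from ``1 - int p``
    (that difference is dominated by the global quadrature error); it is
    estimated by exponential extrapolation of the density's end slope, with
    ``max(1 - int p, 0)`` as fallback when the tail is not decaying."""
    tail = -cumulative_trapezoid(p[::-1], r[::-1], initial=0.0)[::-1]
    leftover = max(1.0 - float(np.trapezoid(p, r)), 0.0)
    if len(p) > 2 and p[-1] > 0 and p[-2] > p[-1]:
        lam = np.log(p[-2] / p[-1]) / (r[-1] - r[-2])
        leftover = float(p[-1] / lam)
    return leftover + tail


def isi_to_hazard(isi: ISIDensity, floor: float = SURVIVOR_FLOOR) -> TabulatedHazard:
    """Hazard quotient ``S = ISI / (1 - int_0^r ISI)`` on the grid.

    The quotient is numerically fragile in the tail, where the survivor
    function underflows and the forward form ``1 - cumtrapz(ISI)`` loses all
    relative accuracy to cancellation.  The survivor is therefore evaluated
    as the backward tail integral (see :func:`_survivor`), which keeps the
    relative error O(dr^2) uniformly.  Where the survivor still drops below
    ``floor`` the hazard is held at its last finite value and the truncation
    age is reported on the returned model.
    """
    r, p = isi.r_grid, isi.density
    if np.any(p < 0):
        raise ValueError("ISI density must be non-negative")
    if float(np.trapezoid(p, r)) > 1.0 + 1e-4:
        raise ValueError(f"ISI density integrates to {np.trapezoid(p, r):.6f} > 1")
    surv = _survivor(r, p)
    ok = surv > floor
    S = np.zeros_like(p)
    S[ok] = p[ok] / surv[ok]
    truncation_age = None
    if not ok.all():
        last = int(np.nonzero(ok)[0][-1]) if ok.any() else 0
        S[last + 1 :] = S[last]
        truncation_age = float(r[last])
    model = TabulatedHazard(r_grid=r, values=S, h0=isi.h)
    model.truncation_age = truncation_age
    return model


def dS_dh_from_isi(
    isi_family,
    h: float,
    r_grid: np.ndarray,
    disi_dh=None,
    delta: float = 1e-4,
    floor: float = SURVIVOR_FLOOR,
) -> np.ndarray:
    """Input-derivative of the hazard from an ISI-density family.

    Implements the quotient

    ``dS/dh = [d_h ISI (1 - int ISI) + ISI int d_h ISI] / (1 - int ISI)^2``

    with ``d_h ISI`` either supplied analytically (``disi_dh(h, r_grid)``)
    or obtained by a central difference of ``isi_family(h, r_grid)`` with
    step ``delta`` (mV).  The same survivor floor as :func:`isi_to_hazard`
    applies; values beyond it are held flat.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    p = np.asarray(isi_family(h, r_grid), dtype=float)
    if disi_dh is not None:
        dp = np.asarray(disi_dh(h, r_grid), dtype=float)
    else:
        hi = np.asarray(isi_family(h + delta, r_grid), dtype=float)
        lo = np.asarray(isi_family(h - delta, r_grid), dtype=float)
        dp = (hi - lo) / (2.0 * delta)
    dF = cumulative_trapezoid(dp, r_grid, initial=0.0)
    surv = _survivor(r_grid, p)
    ok = surv > floor
    out = np.zeros_like(p)
    out[ok] = (dp[ok] * surv[ok] + p[ok] * dF[ok]) / surv[ok] ** 2
    if np.any(~ok):
        last = np.nonzero(ok)[0][-1]
        out[last + 1 :] = out[last]
    return out
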