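"""Direct phase-resetting measurements, the validation surface for the
adjoint mPRC.

A square current pulse is applied at a known phase of the oscillation and
the asymptotic timing shift of the rhythm is read from Poincare crossings
(mean-field) or population-activity peaks (spiking network).  Convention:
positive response = phase advance (subsequent cycle markers arrive earlier).
Time shifts convert to radians via the unperturbed mean-field period,
``dtheta = 2 pi dt_shift / T``.

For comparison with the adjoint ``Z_Is`` (rad per mV of synaptic-current
displacement) the measured shift is divided by the effective charge of the
pulse: ``amplitude * duration / tau_s`` for the synaptic route (the pulse
drives ``tau_s dI_s/dt``), ``amplitude * duration`` for the external route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .hazards import HazardModel
from .meanfield import LimitCycle, MeanFieldSolver, SquarePulse, _upward_crossings
from .network import NetworkParams, simulate_network

__all__ = [
    "PRCCurve",
    "perturb_meanfield",
    "measure_prc_meanfield",
    "perturb_spiking",
    "measure_prc_spiking",
    "smoothed_peaks",
]


@dataclass
class PRCCurve:
    """A PRC sampled on phases in [0, 2 pi)."""

    theta: np.ndarray
    response: np.ndarray
    sem: np.ndarray | None = None
    stimulus: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("PRC response contains non-finite values")

    def __call__(self, theta) -> np.ndarray:
        """Periodic linear interpolation."""
        th = np.mod(theta, 2.0 * np.pi)
        xp = np.concatenate([self.theta, [self.theta[0] + 2.0 * np.pi]])
        fp = np.concatenate([self.response, [self.response[0]]])
        return np.interp(th, xp, fp)

    def to_csv(self, path) -> None:
        cols = [self.theta, self.response]
        header = "theta_rad,response"
        if self.sem is not None:
            cols.append(self.sem)
            header += ",sem"
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
                   comments="")


def perturb_meanfield(
    cycle: LimitCycle,
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    tau_s: float,
    phase: float,
    amplitude: float,
    duration: float,
    n_periods: int = 8,
    route: str = "synaptic",
    decay: str = "linear",
) -> float:
    """Asymptotic phase shift (rad) of the mean-field rhythm for one pulse.

    Two trajectories start from the on-cycle state at phase 0; one receives
    a square pulse whose *center* sits at the requested phase (so a finite
    pulse samples the PRC symmetrically around it).  After the transient has
    relaxed back to the cycle, the shift is the averaged difference of the
    last Poincare-crossing times, in radians via ``2 pi / T``.
    """
    T = cycle.T
    dt = cycle.dt
    solver = MeanFieldSolver(
        hazard, I_ext, J_s, tau_s, dt, r_max=cycle.r_grid[-1], decay=decay
    )
    total = (n_periods + 2) * T
    onset = np.mod(phase, 2 * np.pi) / (2 * np.pi) * T - duration / 2.0
    if onset < 0:
        onset += T
    pulse = SquarePulse(
        onset=onset,
        duration=duration,
        amplitude=amplitude,
        route=route,
    )
    s_ref = cycle.state_at(0)
    s_pert = cycle.state_at(0)
    t_r, _, Is_r = solver.run(s_ref, total)
    t_p, _, Is_p = solver.run(s_pert, total, pulse=pulse)
    level = float(np.mean(cycle.I_s))
    # only crossings well after the pulse transient
    t_min = pulse.onset + pulse.duration + 5.0 * T
    cr_r = _upward_crossings(t_r, Is_r, level)
    cr_p = _upward_crossings(t_p, Is_p, level)
    cr_r = cr_r[cr_r > t_min]
    cr_p = cr_p[cr_p > t_min]
    if len(cr_r) == 0 or len(cr_p) == 0:
        raise RuntimeError(
            "perturbed trajectory shows no late Poincare crossings; "
            "pulse may have left the oscillation's basin"
        )
    k = min(len(cr_r), len(cr_p), 3)
    shifts = cr_r[-k:] - cr_p[-k:]
    # map to the principal branch (small perturbations stay well inside)
    shifts = (shifts + T / 2) % T - T / 2
    return float(2.0 * np.pi * np.mean(shifts) / T)


def measure_prc_meanfield(
    cycle: LimitCycle,
    hazard: HazardModel,
    I_ext: float,
    J_s: float,
    tau_s: float,
    amplitude: float = 0.8,
    duration: float = 0.8,
    n_phases: int = 16,
    route: str = "synaptic",
    decay: str = "linear",
) -> PRCCurve:
    """Sweep pulse phases and scale shifts per unit effective charge, making
    the result directly comparable with the adjoint ``Z_Is``."""
    thetas = 2.0 * np.pi * np.arange(n_phases) / n_phases
    shifts = np.array(
        [
            perturb_meanfield(
                cycle, hazard, I_ext, J_s, tau_s, th, amplitude, duration,
                route=route, decay=decay,
            )
            for th in thetas
        ]
    )
    charge = amplitude * duration / (tau_s if route == "synaptic" else 1.0)
    return PRCCurve(
        theta=thetas,
        response=shifts / charge,
        stimulus={"amplitude": amplitude, "duration": duration, "route": route,
                  "shape": "square"},
    )


def smoothed_peaks(
    t: np.ndarray, A: np.ndarray, T: float, sigma_factor: float = 1.0 / 20.0
) -> np.ndarray:
    """Peak times of the population activity smoothed with a Gaussian kernel
    of width ``sigma = T * sigma_factor``."""
    dt = t[1] - t[0]
    sm = gaussian_filter1d(A, sigma=max(T * sigma_factor / dt, 1.0))
    idx, _ = find_peaks(sm, distance=max(int(0.6 * T / dt), 1))
    return t[idx]


def estimate_period(t: np.ndarray, A: np.ndarray) -> float:
    """Dominant oscillation period from the activity power spectrum."""
    dt = t[1] - t[0]
    x = A - np.mean(A)
    f = np.fft.rfftfreq(len(x), dt)
    p = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    k = np.argmax(p[1:]) + 1
    return 1.0 / f[k]


def perturb_spiking(
    params: NetworkParams,
    phase: float,
    amplitude: float,
    duration: float,
    n_trials: int = 20,
    seed: int = 0,
    T_hint: float | None = None,
    warmup: float = 300.0,
    n_post_periods: int = 6,
    route: str = "synaptic",
) -> tuple[float, float]:
    """Trial-averaged phase shift (rad) +/- SEM from paired spiking runs.

    Per trial, an unperturbed network is simulated and its smoothed-activity
    peaks define the ongoing phase; the paired run (same RNG seed, hence
    identical until the pulse) receives a square pulse at the requested
    phase relative to a post-warmup anchor peak.  The shift is the circular
    mean of the peak-time differences 4..``n_post_periods`` periods later.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    shifts = []
    for trial in range(n_trials):
        p = NetworkParams(**{**params.__dict__, "seed": seed + 1000 * trial})
        T0 = T_hint
        dur = warmup + (n_post_periods + 8) * (T0 or 25.0)
        ref = simulate_network(p, dur)
        if T0 is None:
            T0 = estimate_period(ref.t, ref.A)
        peaks_ref = smoothed_peaks(ref.t, ref.A, T0)
        anchors = peaks_ref[peaks_ref > warmup]
        if len(anchors) < n_post_periods + 4:
            raise RuntimeError(
                "oscillation too noisy to anchor the stimulus phase; "
                "increase N or duration"
            )
        t_on = anchors[0] + np.mod(phase, 2 * np.pi) / (2 * np.pi) * T0 - duration / 2.0
        pulse = SquarePulse(onset=t_on, duration=duration, amplitude=amplitude,
                            route=route)
        pert = simulate_network(p, dur, perturbation=pulse)
        peaks_p = smoothed_peaks(pert.t, pert.A, T0)
        t_min = t_on + duration + 3.0 * T0
        late_ref = peaks_ref[peaks_ref > t_min]
        late_p = peaks_p[peaks_p > t_min]
        k = min(len(late_ref), len(late_p), 4)
        if k == 0:
            raise RuntimeError("no post-pulse activity peaks found")
        d = late_ref[-k:] - late_p[-k:]
        d = (d + T0 / 2) % T0 - T0 / 2
        shifts.append(2.0 * np.pi * np.mean(d) / T0)
    shifts = np.asarray(shifts)
    sem = float(np.std(shifts, ddof=1) / np.sqrt(len(shifts))) if len(shifts) > 1 else 0.0
    return float(np.mean(shifts)), sem


def measure_prc_spiking(
    params: NetworkParams,
    amplitude: float = 3.0,
    duration: float = 5.0,
    n_phases: int = 8,
    n_trials: int = 20,
    seed: int = 0,
    T_hint: float | None = None,
    route: str = "synaptic",
) -> PRCCurve:
    """Phase sweep of :func:`perturb_spiking`, scaled per unit effective
    charge like the mean-field curve."""
    thetas = 2.0 * np.pi * np.arange(n_phases) / n_phases
    means, sems = [], []
    for th in thetas:
        m, s = perturb_spiking(
            params, th, amplitude, duration, n_trials=n_trials, seed=seed,
            T_hint=T_hint, route=route,
        )
        means.append(m)
        sems.append(s)
    charge = amplitude * duration / (params.tau_s if route == "synaptic" else 1.0)
    return PRCCurve(
        theta=thetas,
        response=np.asarray(means) / charge,
        sem=np.asarray(sems) / charge,
        stimulus={"amplitude": amplitude, "duration": duration, "route": route,
                  "shape": "square"},
    )
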