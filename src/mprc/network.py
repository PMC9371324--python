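"""Finite-N stochastic simulation of the renewal spiking network.

Each of the ``N`` neurons carries an age ``r`` (time since its last spike)
and fires in ``[t, t+dt)`` with probability ``1 - exp(-Lambda)``, where
``Lambda = int_t^{t+dt} S(h, r+s) ds`` is the integrated hazard across the
step (trapezoid in age).  When a neuron fires, the spike time is drawn from
the conditional within-step distribution and the age is reset relative to
that time, so interspike-interval statistics are exact to second order in
``dt`` rather than first.  All-to-all coupling acts through one shared
synaptic current: every spike increments ``I_s`` by ``J_s/(N tau_s)`` and
``I_s`` decays by the exact factor ``exp(-dt/tau_s)`` between steps; spikes
affect ``h`` from the next step on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hazards import HazardModel
from .meanfield import SquarePulse

__all__ = [
    "NetworkParams",
    "SpikeRaster",
    "SimResult",
    "simulate_network",
    "simulate_coupled",
    "population_activity",
]


@dataclass
class NetworkParams:
    """Parameters of one recurrent circuit."""

    hazard: HazardModel
    N: int = 5000
    J_s: float = 15.0  # mV ms
    tau_s: float = 10.0  # ms
    dt: float = 0.05  # ms
    I_ext: float = 2.0  # mV (scalar or callable of t)
    seed: int = 0
    age_init_mean: float | None = None  # default T_ref/2
    age_init_std: float | None = None  # default T_ref/6

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.dt <= 0 or self.tau_s <= 0:
            raise ValueError("dt and tau_s must be positive")


@dataclass
class SpikeRaster:
    """All spikes of one run: parallel arrays of times (ms) and neuron ids."""

    times: np.ndarray
    ids: np.ndarray
    N: int
    duration: float

    def per_neuron(self) -> list[np.ndarray]:
        order = np.argsort(self.ids, kind="stable")
        ids, times = self.ids[order], self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.N + 1))
        return [np.sort(times[bounds[k] : bounds[k + 1]]) for k in range(self.N)]

    def isis(self) -> np.ndarray:
        return np.concatenate([np.diff(ts) for ts in self.per_neuron() if len(ts) > 1])

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.ids, self.times]),
            delimiter=",",
            header="neuron_id,spike_time_ms",
            comments="",
            fmt=["%d", "%.6f"],
        )

    @classmethod
    def from_csv(cls, path, N: int, duration: float) -> "SpikeRaster":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            return cls(np.array([]), np.array([], dtype=int), N, duration)
        return cls(data[:, 1], data[:, 0].astype(int), N, duration)


@dataclass
class SimResult:
    raster: SpikeRaster
    t: np.ndarray  # step-end times
    A: np.ndarray  # per-step population activity (1/ms)
    I_s: np.ndarray  # synaptic current at step ends
    params: NetworkParams | None = None


class _Circuit:
    """Stepping state of one network (ages, synapse, spike buffer)."""

    def __init__(self, params: NetworkParams, rng: np.random.Generator):
        self.p = params
        hz = params.hazard
        t_ref = hz.t_ref if hz.t_ref > 0 else 1.0
        mean = params.age_init_mean if params.age_init_mean is not None else t_ref / 2
        std = params.age_init_std if params.age_init_std is not None else t_ref / 6
        self.ages = np.maximum(rng.normal(mean, std, params.N), 0.0)
        self.I_s = 0.0
        self.I_ext = (
            params.I_ext if callable(params.I_ext) else (lambda t, v=float(params.I_ext): v)
        )
        self.sep = hz.separable
        self.spike_t: list[np.ndarray] = []
        self.spike_id: list[np.ndarray] = []
        self._decay = np.exp(-params.dt / params.tau_s)

    def integrated_hazard(self, h: float) -> np.ndarray:
        """Trapezoid of S(h, r) over the step for every neuron."""
        dt = self.p.dt
        hz = self.p.hazard
        if self.sep:
            lam = np.exp(h) * 0.5 * (hz.shape(self.ages) + hz.shape(self.ages + dt))
        else:
            lam = 0.5 * (hz.rate(h, self.ages) + hz.rate(h, self.ages + dt))
        return lam * dt

    def step(self, t: float, rng: np.random.Generator, h_extra: float = 0.0,
             I_s_extra: float = 0.0) -> int:
        """Advance one step; returns the number of spikes fired.

        ``h_extra`` is added to the input (external pulse route);
        ``I_s_extra`` is an extra increment of the synaptic current this
        step (synaptic pulse route / cross-circuit input), applied after
        firing so it acts from the next step on.
        """
        dt = self.p.dt
        h = self.I_ext(t) + self.I_s + h_extra
        Lam = self.integrated_hazard(h)
        prob = -np.expm1(-Lam)
        u = rng.random(self.p.N)
        fired = u < prob
        n_fired = int(np.count_nonzero(fired))
        self.ages += dt
        if n_fired:
            # conditional spike time within the step: invert the truncated
            # exponential at rate Lambda/dt using the same uniform draw
            v = u[fired] / prob[fired]
            lam_f = Lam[fired]
            s = np.where(
                lam_f > 1e-12,
                -np.log1p(-v * prob[fired]) * (dt / lam_f),
                v * dt,
            )
            self.spike_t.append(t + s)
            self.spike_id.append(np.nonzero(fired)[0])
            self.ages[fired] = dt - s
        self.I_s = self.I_s * self._decay + n_fired * self.p.J_s / (
            self.p.N * self.p.tau_s
        ) + I_s_extra
        return n_fired

    def raster(self, duration: float) -> SpikeRaster:
        if self.spike_t:
            times = np.concatenate(self.spike_t)
            ids = np.concatenate(self.spike_id)
        else:
            times = np.array([])
            ids = np.array([], dtype=int)
        return SpikeRaster(times, ids, self.p.N, duration)


def simulate_network(
    params: NetworkParams,
    duration: float,
    perturbation: SquarePulse | None = None,
) -> SimResult:
    """Simulate one circuit for ``duration`` ms.

    ``perturbation`` is an optional square pulse; its ``route`` decides
    whether it adds to ``h`` directly (``"external"``) or drives the
    ``tau_s dI_s/dt`` equation (``"synaptic"``).
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one step")
    rng = np.random.default_rng(params.seed)
    net = _Circuit(params, rng)
    n = int(round(duration / params.dt))
    t_out = np.empty(n)
    A = np.empty(n)
    Is = np.empty(n)
    dt = params.dt
    for i in range(n):
        t = i * dt
        h_extra = 0.0
        is_extra = 0.0
        if perturbation is not None:
            val = perturbation.value(t)
            if perturbation.route == "external":
                h_extra = val
            else:
                is_extra = val * dt / params.tau_s
        n_f = net.step(t, rng, h_extra=h_extra, I_s_extra=is_extra)
        t_out[i] = t + dt
        A[i] = n_f / (params.N * dt)
        Is[i] = net.I_s
    return SimResult(net.raster(duration), t_out, A, Is, params)


def simulate_coupled(
    params1: NetworkParams,
    params2: NetworkParams,
    G_s: float,
    delay: float,
    duration: float,
    eps: float = 1.0,
    seed: int | None = None,
) -> tuple[SimResult, SimResult]:
    """Two circuits with symmetric delayed cross-coupling.

    The synaptic equations become
    ``tau_s dI_s1/dt = -I_s1 + J_s A1 + eps G_s A2(t - d)`` (and symmetric),
    implemented as per-spike increments ``eps G_s/(N tau_s)`` read from a
    delay buffer of ``round(d/dt)`` steps.  One RNG (from ``seed``, default
    ``params1.seed``) drives both circuits.
    """
    if params1.dt != params2.dt:
        raise ValueError("both circuits must share dt")
    dt = params1.dt
    rng = np.random.default_rng(params1.seed if seed is None else seed)
    net1 = _Circuit(params1, rng)
    net2 = _Circuit(params2, rng)
    n = int(round(duration / dt))
    L = max(1, int(round(delay / dt)))
    buf1 = np.zeros(n + L, dtype=int)  # spike counts of circuit 1 per step
    buf2 = np.zeros(n + L, dtype=int)
    out = []
    for net in (net1, net2):
        out.append({"t": np.empty(n), "A": np.empty(n), "Is": np.empty(n)})
    g1 = eps * G_s / (params1.N * params1.tau_s)
    g2 = eps * G_s / (params2.N * params2.tau_s)
    for i in range(n):
        t = i * dt
        cross1 = g2 * buf2[i]  # into circuit 1: spikes of 2 at t - d
        cross2 = g1 * buf1[i]
        n1 = net1.step(t, rng, I_s_extra=cross1)
        n2 = net2.step(t, rng, I_s_extra=cross2)
        buf1[i + L] = n1
        buf2[i + L] = n2
        for o, nf, net in ((out[0], n1, net1), (out[1], n2, net2)):
            o["t"][i] = t + dt
            o["A"][i] = nf / (net.p.N * dt)
            o["Is"][i] = net.I_s
    res = []
    for o, net, p in ((out[0], net1, params1), (out[1], net2, params2)):
        res.append(SimResult(net.raster(duration), o["t"], o["A"], o["Is"], p))
    return res[0], res[1]


def population_activity(
    raster: SpikeRaster, bin_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Binned population activity ``A_N`` (1/ms): spike counts over
    ``N * bin``.  Returns bin centers and values; an empty raster gives an
    all-zero series."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    edges = np.arange(0.0, raster.duration + bin_ms, bin_ms)
    counts, _ = np.histogram(raster.times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (raster.N * bin_ms)
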