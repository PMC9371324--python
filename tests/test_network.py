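"""Stochastic renewal-network simulator."""

import numpy as np
import pytest

from mprc import (
    NetworkParams,
    make_preset,
    population_activity,
    simulate_network,
    steady_state,
)
from mprc.network import SpikeRaster


def _params(hz, **over):
    base = dict(hazard=hz, N=400, J_s=0.0, tau_s=10.0, dt=0.02, I_ext=0.0, seed=5)
    base.update(over)
    return NetworkParams(**base)


def test_silent_network_decays_synapse_only():
    """S = 0 everywhere reachable: no spikes, I_s decays exactly."""
    hz = make_preset("exp_relax", t_ref=1e6, tau=0.0)
    p = _params(hz, N=50)
    res = simulate_network(p, 10.0)
    assert len(res.raster.times) == 0
    assert np.all(res.A == 0.0)
    t, A = population_activity(res.raster, 1.0)
    assert np.all(A == 0.0)


def test_shifted_exponential_isi_statistics():
    """S = s H(r - T_ref), J_s = 0: mean ISI = T_ref + 1/s within 3 SEM."""
    hz = make_preset("exp_relax", t_ref=5.0, tau=0.0)
    p = _params(hz, N=600, seed=3)
    res = simulate_network(p, 900.0)
    isis = res.raster.isis()
    sem = isis.std(ddof=1) / np.sqrt(len(isis))
    assert abs(isis.mean() - 6.0) < 3.0 * sem
    # refractoriness up to one step of discretization
    assert isis.min() > 5.0 - p.dt


def test_poisson_rate_recovers_hazard():
    """Memoryless hazard: time-averaged activity = s within 3 SEM."""
    hz = make_preset("exp_relax", t_ref=0.0, tau=0.0)
    p = _params(hz, N=500, I_ext=np.log(0.2), seed=11)
    res = simulate_network(p, 400.0)
    n = len(res.raster.times)
    rate = n / (p.N * 400.0)
    sem = np.sqrt(n) / (p.N * 400.0)
    assert abs(rate - 0.2) < 3.0 * sem


def test_rebinning_conserves_spike_count():
    hz = make_preset("exp_relax", t_ref=5.0, tau=0.0)
    res = simulate_network(_params(hz, N=200, seed=9), 200.0)
    for bin_ms in (0.5, 1.0, 2.0):
        t, A = population_activity(res.raster, bin_ms)
        total = np.sum(A) * 200 * bin_ms
        assert total == pytest.approx(len(res.raster.times), abs=0.5)


def test_single_spike_activity_normalization():
    raster = SpikeRaster(np.array([3.2]), np.array([0]), N=1, duration=10.0)
    _, A = population_activity(raster, 1.0)
    assert A[3] == pytest.approx(1.0)
    assert np.sum(A) == pytest.approx(1.0)


def test_same_seed_reproducible():
    hz = make_preset("exp_relax", t_ref=5.0, tau=2.0)
    a = simulate_network(_params(hz, J_s=5.0, I_ext=1.0, seed=42), 100.0)
    b = simulate_network(_params(hz, J_s=5.0, I_ext=1.0, seed=42), 100.0)
    assert np.array_equal(a.raster.times, b.raster.times)
    assert np.array_equal(a.I_s, b.I_s)


def test_network_rate_matches_meanfield_steady_state():
    """N = 5000 recurrent network in the asynchronous regime reproduces
    A_inf within 3 SEM (batch-mean errors to respect autocorrelation)."""
    hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
    ss = steady_state(hz, 0.5, 1.0)
    p = NetworkParams(hazard=hz, N=5000, J_s=1.0, tau_s=10.0, dt=0.02,
                      I_ext=0.5, seed=7)
    res = simulate_network(p, 500.0)
    tt = res.raster.times
    edges = np.linspace(100.0, 500.0, 9)
    batch = np.array(
        [np.sum((tt >= a) & (tt < b)) / (p.N * (b - a))
         for a, b in zip(edges[:-1], edges[1:])]
    )
    sem = batch.std(ddof=1) / np.sqrt(len(batch))
    assert abs(batch.mean() - ss.A_inf) < 3.0 * sem


def test_raster_csv_roundtrip(tmp_path):
    hz = make_preset("exp_relax", t_ref=5.0, tau=0.0)
    res = simulate_network(_params(hz, N=50, seed=2), 60.0)
    path = tmp_path / "raster.csv"
    res.raster.to_csv(path)
    again = SpikeRaster.from_csv(path, N=50, duration=60.0)
    assert np.allclose(again.times, res.raster.times, atol=1e-6)
    assert np.array_equal(again.ids, res.raster.ids)
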