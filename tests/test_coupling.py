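"""Weakly-coupled-oscillator interaction functions and locking prediction."""

import numpy as np
import pytest

from mprc.coupling import (
    circular_distance,
    delay_bifurcation,
    empirical_phase_lag,
    g_function,
    interaction_H,
)
from mprc.network import SimResult, SpikeRaster


@pytest.fixture()
def synthetic_cycle():
    """A smooth one-period activity and PRC on a shared grid."""
    M, T = 400, 10.0
    th = 2 * np.pi * np.arange(M) / M
    A = 0.1 + 0.08 * np.cos(th) + 0.03 * np.sin(2 * th)
    Z = 0.15 + 0.05 * np.sin(th + 0.7)
    return th, A, Z, T, M


def test_constant_prc_gives_flat_H_and_zero_G(synthetic_cycle):
    th, A, _, T, M = synthetic_cycle
    H = interaction_H(np.full(M, 0.2), A, T, 0.2)
    assert np.allclose(H, 0.2 * 0.2 * A.mean(), rtol=1e-12)
    pi = g_function(H, T, d=1.3)
    assert np.max(np.abs(pi.G)) < 1e-15
    assert pi.fixed_points == []


def test_H_linear_in_coupling_strength(synthetic_cycle):
    th, A, Z, T, _ = synthetic_cycle
    H1 = interaction_H(Z, A, T, 0.2)
    H2 = interaction_H(Z, A, T, 0.4)
    assert np.allclose(H2, 2.0 * H1)


def test_H_against_dense_oracle(synthetic_cycle):
    """FFT circular correlation vs a direct double loop."""
    th, A, Z, T, M = synthetic_cycle
    H = interaction_H(Z, A, T, 0.2)
    dts = T / M
    oracle = np.array(
        [0.2 / T * np.sum(Z * A[(np.arange(M) - k) % M]) * dts for k in range(M)]
    )
    assert np.max(np.abs(H - oracle)) < 1e-12


def test_g_identity_against_dense_oracle(synthetic_cycle):
    th, A, Z, T, M = synthetic_cycle
    H = interaction_H(Z, A, T, 0.2)
    pi = g_function(H, T, d=2.2)
    t = pi.t_grid

    def Hf(x):
        xp = np.concatenate([t, [T]])
        fp = np.concatenate([H, [H[0]]])
        return np.interp(np.mod(x, T), xp, fp)

    assert np.max(np.abs(pi.G - (Hf(t - 2.2) - Hf(-t - 2.2)))) < 1e-12


def test_zero_delay_G_is_odd_with_structural_zeros(synthetic_cycle):
    """d = 0: G is odd, so in-phase and anti-phase are always fixed points."""
    th, A, Z, T, M = synthetic_cycle
    H = interaction_H(Z, A, T, 0.2)
    pi = g_function(H, T, d=0.0)
    assert abs(np.sum(pi.G)) < 1e-10  # odd function: circular mean vanishes
    lags = sorted(fp.theta_ms for fp in pi.fixed_points)
    assert any(min(l, T - l) < T / M for l in lags)  # theta = 0
    assert any(abs(l - T / 2) < T / M for l in lags)  # theta = T/2


def test_stability_labels_alternate(synthetic_cycle):
    th, A, Z, T, _ = synthetic_cycle
    H = interaction_H(Z, A, T, 0.2)
    for pi in delay_bifurcation(H, T, [0.5, 2.5, 4.5]):
        labels = [fp.stable for fp in pi.fixed_points]
        if len(labels) > 1:
            assert all(a != b for a, b in zip(labels, labels[1:]))
            assert labels[0] != labels[-1]  # alternation closes on the circle


def test_fixed_points_invariant_under_strength(synthetic_cycle):
    """Halving eps*G_s halves G but leaves the zeros in place."""
    th, A, Z, T, _ = synthetic_cycle
    pi1 = g_function(interaction_H(Z, A, T, 0.2), T, d=2.5)
    pi2 = g_function(interaction_H(Z, A, T, 0.1), T, d=2.5)
    assert np.allclose(pi1.G, 2.0 * pi2.G)
    z1 = sorted(fp.theta_ms for fp in pi1.fixed_points)
    z2 = sorted(fp.theta_ms for fp in pi2.fixed_points)
    assert np.allclose(z1, z2, atol=1e-9)


def _fake_simresult(peak_times, T, duration, dt=0.05):
    """Synthetic oscillatory activity with peaks at known times."""
    t = np.arange(dt, duration + dt / 2, dt)
    A = np.zeros_like(t)
    for pt in peak_times:
        A += np.exp(-0.5 * ((t - pt) / (T / 12)) ** 2)
    raster = SpikeRaster(np.array([]), np.array([], dtype=int), N=1,
                         duration=duration)
    return SimResult(raster, t, A, np.zeros_like(t))


def test_empirical_phase_lag_recovers_known_offset():
    T, dur = 10.0, 300.0
    base = np.arange(15.0, dur - 5.0, T)
    r1 = _fake_simresult(base, T, dur)
    r2 = _fake_simresult(base - 2.5, T, dur)  # circuit 2 leads by 2.5 ms
    lag, sd = empirical_phase_lag(r1, r2, T)
    assert lag == pytest.approx(2.5, abs=0.1)
    assert sd < 0.1


def test_circular_distance():
    assert circular_distance(9.5, 0.5, 10.0) == pytest.approx(1.0)
    assert circular_distance(2.0, 7.0, 10.0) == pytest.approx(5.0)
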