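"""Mean-field PDE integration, steady states and limit-cycle extraction."""

import numpy as np
import pytest

from mprc import (
    MeanFieldSolver,
    NoOscillationError,
    find_limit_cycle,
    make_preset,
    steady_state,
)


def test_pure_transport_advects_density():
    """With S = 0 on the grid a bump advects at unit speed, mass constant."""
    hz = make_preset("exp_relax", t_ref=50.0, tau=0.0)  # inactive on the grid
    solver = MeanFieldSolver(hz, 0.0, 0.0, 10.0, dt=0.05, r_max=20.0)
    state = solver.new_state()
    q0 = state.q.copy()
    m0 = state.mass()
    solver.run(state, 5.0)
    shift = int(round(5.0 / 0.05))
    assert np.allclose(state.q[shift:], q0[:-shift])
    assert state.mass() == pytest.approx(m0, abs=1e-13)


def test_constant_hazard_truncated_steady_profile():
    """Constant S = s relaxes to A exp(-s r) with A = s/(1 - exp(-s r_max))."""
    hz = make_preset("exp_relax", t_ref=0.0, tau=0.0)  # S = exp(h), h = 0
    r_max = 8.0
    solver = MeanFieldSolver(hz, 0.0, 0.0, 10.0, dt=0.005, r_max=r_max)
    state = solver.new_state()
    solver.run(state, 200.0)
    A_pred = 1.0 / (1.0 - np.exp(-r_max))
    assert state.q[0] == pytest.approx(A_pred, rel=2e-3)
    # the scheme's exact discrete profile is geometric in the survival factor
    j = np.arange(len(solver.r_grid))
    assert np.allclose(state.q, state.q[0] * (1.0 - 0.005) ** j, rtol=1e-3)
    # and first-order close to the continuum exponential
    assert np.allclose(state.q, state.q[0] * np.exp(-solver.r_grid),
                       rtol=3e-2, atol=1e-4)


def test_mass_exactly_conserved(fig3_hazard):
    solver = MeanFieldSolver(fig3_hazard, 2.0, 15.0, 10.0, dt=0.05)
    state = solver.new_state()
    for _ in range(4):
        solver.run(state, 50.0)
        assert abs(state.mass() - 1.0) < 1e-12


def test_boundary_identity(fig3_hazard):
    """q(t, 0) equals the reported activity at every step by construction."""
    solver = MeanFieldSolver(fig3_hazard, 2.0, 15.0, 10.0, dt=0.05)
    state = solver.new_state()
    _, A, _ = solver.run(state, 20.0)
    assert state.q[0] == A[-1]


def test_steady_state_closed_form_decoupled():
    """J_s = 0, Heaviside hazard: A_inf = 1/(T_ref + exp(-I_ext))."""
    hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
    ss = steady_state(hz, 2.0, 0.0)
    assert ss.A_inf == pytest.approx(1.0 / (8.0 + np.exp(-2.0)), abs=1e-12)
    assert abs(ss.residual) < 1e-10
    assert ss.q_inf[0] == pytest.approx(ss.A_inf)
    assert np.trapezoid(ss.q_inf, ss.r_grid) == pytest.approx(1.0, abs=1e-5)


def test_steady_state_recurrent_residual():
    """With recurrent coupling the self-consistent residual still vanishes."""
    hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
    ss = steady_state(hz, 2.0, 1.0)
    assert abs(ss.residual) < 1e-10
    assert ss.h_inf == pytest.approx(2.0 + ss.A_inf)


def test_steady_state_general_quadrature_smooth_hazard(fig3_hazard):
    """For tau > 0 the quadrature route must satisfy its own equation."""
    ss = steady_state(fig3_hazard, 2.0, 0.0, dr=5e-4)
    S = fig3_hazard.rate(ss.h_inf, ss.r_grid)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (S[1:] + S[:-1]) * np.diff(ss.r_grid))]
    )
    mean_isi = np.trapezoid(np.exp(-cum), ss.r_grid)
    assert ss.A_inf * mean_isi == pytest.approx(1.0, abs=1e-10)


def test_asynchronous_average_matches_steady_state():
    """Time-averaged mean-field activity equals A_inf in the stable regime."""
    hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
    ss = steady_state(hz, 2.0, 1.0)
    solver = MeanFieldSolver(hz, 2.0, 1.0, 10.0, dt=0.1)
    state = solver.new_state()
    solver.run(state, 500.0)
    _, A, _ = solver.run(state, 800.0)
    assert np.mean(A) == pytest.approx(ss.A_inf, rel=1e-2)


def test_limit_cycle_fig3(fig3_cycle):
    assert 8.0 < fig3_cycle.T < 14.0
    assert fig3_cycle.periodicity_error < 1e-3
    # boundary condition holds on every stored snapshot
    assert np.allclose(fig3_cycle.q[:, 0], fig3_cycle.A, rtol=1e-10)
    # phase-0 anchor: I_s sits at its mean level and is rising at sample 0
    level = fig3_cycle.I_s.mean()
    assert abs(fig3_cycle.I_s[0] - level) < 0.02 * np.ptp(fig3_cycle.I_s)
    assert fig3_cycle.I_s[-1] < fig3_cycle.I_s[0] < fig3_cycle.I_s[1]


def test_limit_cycle_period_robust_to_measure_window(fig3_hazard):
    a = find_limit_cycle(
        fig3_hazard, 2.0, 15.0, 10.0, 0.02, t_transient=1200.0, t_measure=200.0
    )
    b = find_limit_cycle(
        fig3_hazard, 2.0, 15.0, 10.0, 0.02, t_transient=1200.0, t_measure=400.0
    )
    assert abs(a.T - b.T) / a.T < 1e-3


def test_first_order_period_convergence(fig3_hazard):
    """Halving dt changes T by an amount consistent with first order."""
    Ts = {
        dt: find_limit_cycle(
            fig3_hazard, 2.0, 15.0, 10.0, dt, t_transient=1000.0, t_measure=250.0
        ).T
        for dt in (0.04, 0.02, 0.01)
    }
    d1 = abs(Ts[0.04] - Ts[0.02])
    d2 = abs(Ts[0.02] - Ts[0.01])
    assert d2 < d1
    assert d1 / max(d2, 1e-12) < 6.0  # roughly factor 2 for first order


def test_no_oscillation_detected_in_asynchronous_regime():
    hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
    with pytest.raises(NoOscillationError):
        find_limit_cycle(hz, 0.5, 2.0, 10.0, 0.05, t_transient=2500.0,
                         t_measure=400.0)


def test_cycle_save_load_roundtrip(fig3_cycle, tmp_path):
    from mprc.meanfield import LimitCycle

    path = tmp_path / "cycle.npz"
    fig3_cycle.save(path)
    again = LimitCycle.load(path)
    assert again.T == fig3_cycle.T
    assert np.array_equal(again.q, fig3_cycle.q)
    assert np.array_equal(again.I_s, fig3_cycle.I_s)
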