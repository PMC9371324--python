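"""Finite network versus mean-field: asynchronous rates agree.

Simulates 5000 stochastic renewal neurons with weak recurrent excitation,
integrates the refractory-density equation with the same parameters, and
compares both time-averaged firing rates with the self-consistent steady
state.
"""

import numpy as np

from mprc import (
    MeanFieldSolver,
    NetworkParams,
    make_preset,
    simulate_network,
    steady_state,
)

hz = make_preset("exp_relax", t_ref=8.0, tau=0.0)
I_ext, J_s, tau_s = 0.5, 1.0, 10.0

ss = steady_state(hz, I_ext, J_s)
print(f"steady state: A_inf = {ss.A_inf:.6f} spikes/ms per neuron "
      f"(h_inf = {ss.h_inf:.4f} mV, residual {ss.residual:.1e})")

solver = MeanFieldSolver(hz, I_ext, J_s, tau_s, dt=0.1)
state = solver.new_state()
solver.run(state, 400.0)  # transient
_, A, _ = solver.run(state, 800.0)
print(f"mean-field time average = {A.mean():.6f} "
      f"({100 * abs(A.mean() / ss.A_inf - 1):.3f}% from A_inf); "
      f"mass error {abs(state.mass() - 1):.1e}")

p = NetworkParams(hazard=hz, N=5000, J_s=J_s, tau_s=tau_s, dt=0.02,
                  I_ext=I_ext, seed=1)
res = simulate_network(p, 400.0)
tt = res.raster.times
rate = np.sum(tt > 100.0) / (p.N * 300.0)
print(f"network (N=5000) time average = {rate:.6f} "
      f"({100 * abs(rate / ss.A_inf - 1):.3f}% from A_inf)")
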