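"""The macroscopic phase-resetting curve of an emergent network rhythm.

Extracts the limit cycle of the reference oscillatory circuit, solves the
adjoint system backward along it, normalizes, and validates the resulting
mPRC against direct square-pulse perturbations of the mean-field.
"""

import numpy as np

from mprc import find_limit_cycle, make_preset, mprc, normalize, solve_adjoint
from mprc.prc import measure_prc_meanfield

hz = make_preset("exp_relax", t_ref=10.0, tau=5.0)
I_ext, J_s, tau_s = 2.0, 15.0, 10.0

cycle = find_limit_cycle(hz, I_ext, J_s, tau_s, 0.01,
                         t_transient=1500.0, t_measure=300.0)
print(f"limit cycle: T = {cycle.T:.4f} ms "
      f"(periodicity error {cycle.periodicity_error:.1e})")

adj = normalize(solve_adjoint(cycle, hz, I_ext, J_s, tau_s), cycle,
                max_deviation=0.05)
curve = mprc(adj)
print(f"adjoint converged in {adj.n_passes} backward periods; "
      f"normalization bracket flat to {adj.bracket_deviation:.2%}")
print(f"mPRC: min = {curve.response.min():.4f}, "
      f"max = {curve.response.max():.4f} rad/mV "
      f"-> one-signed (type I): every input advances the rhythm")

direct = measure_prc_meanfield(cycle, hz, I_ext, J_s, tau_s,
                               amplitude=0.8, duration=0.8, n_phases=8)
r = np.corrcoef(curve(direct.theta), direct.response)[0, 1]
print("\nphase   adjoint Z_Is   direct pulse")
for th, d in zip(direct.theta, direct.response):
    print(f"{th:5.2f}   {float(curve(th)):12.4f}   {d:12.4f}")
print(f"Pearson r (adjoint vs direct) = {r:.4f}")
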