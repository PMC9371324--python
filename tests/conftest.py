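import numpy as np
import pytest

from mprc import find_limit_cycle, make_preset, normalize, solve_adjoint

# reference oscillatory circuit: exp-relax hazard, strong recurrent excitation
FIG3 = dict(I_ext=2.0, J_s=15.0, tau_s=10.0)


@pytest.fixture(scope="session")
def fig3_hazard():
    return make_preset("exp_relax", t_ref=10.0, tau=5.0)


@pytest.fixture(scope="session")
def fig3_cycle(fig3_hazard):
    """Working-resolution limit cycle (dt = 0.01 ms) shared across tests."""
    return find_limit_cycle(
        fig3_hazard, FIG3["I_ext"], FIG3["J_s"], FIG3["tau_s"], 0.01,
        t_transient=1500.0, t_measure=300.0,
    )


@pytest.fixture(scope="session")
def fig3_adjoint(fig3_cycle, fig3_hazard):
    adj = solve_adjoint(
        fig3_cycle, fig3_hazard, FIG3["I_ext"], FIG3["J_s"], FIG3["tau_s"]
    )
    return normalize(adj, fig3_cycle, max_deviation=0.05)
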