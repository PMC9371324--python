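"""Run configuration, YAML I/O and the named parameter fixtures.

Fixtures ``fig1`` .. ``fig5`` carry the hazard form and the network/solver
parameters of the corresponding study conditions, addressable by name from
the CLI and the examples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .coupling import CouplingSpec
from .hazards import HazardModel, make_preset
from .meanfield import default_r_max
from .network import NetworkParams

__all__ = ["HazardSpec", "SolverSpec", "RunConfig", "load_config", "dump_config",
           "make_fixture", "FIXTURES"]


class ConfigError(ValueError):
    pass


def _strict_build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


@dataclass
class HazardSpec:
    form: str = "exp_relax"
    params: dict = field(default_factory=lambda: {"t_ref": 10.0, "tau": 5.0})

    def build(self) -> HazardModel:
        return make_preset(self.form, **self.params)


@dataclass
class SolverSpec:
    dt: float = 0.05  # forward-integration step / age-grid spacing (ms)
    adjoint_dt: float = 0.005  # step used when the cycle feeds the adjoint
    r_max: float | None = None  # default 1.25 * T_ref
    t_transient: float = 800.0
    t_measure: float = 400.0
    cycle_tol: float = 5e-3
    adjoint_tol: float = 1e-6
    n_cycles: int = 50

    def __post_init__(self):
        for key in ("dt", "adjoint_dt", "t_transient", "t_measure", "cycle_tol",
                    "adjoint_tol"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"solver.{key} must be positive")


@dataclass
class RunConfig:
    hazard: HazardSpec = field(default_factory=HazardSpec)
    I_ext: float = 2.0
    J_s: float = 15.0
    tau_s: float = 10.0
    N: int = 5000
    seed: int = 0
    solver: SolverSpec = field(default_factory=SolverSpec)
    coupling: CouplingSpec | None = None
    extras: dict = field(default_factory=dict)
    outdir: str = "."

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ConfigError("tau_s must be positive")
        if self.N < 1:
            raise ConfigError("N must be >= 1")

    def build_hazard(self) -> HazardModel:
        return self.hazard.build()

    def r_max(self) -> float:
        if self.solver.r_max is not None:
            return self.solver.r_max
        return default_r_max(self.build_hazard(), self.I_ext)

    def network_params(self, dt: float | None = None) -> NetworkParams:
        return NetworkParams(
            hazard=self.build_hazard(),
            N=self.N,
            J_s=self.J_s,
            tau_s=self.tau_s,
            dt=dt if dt is not None else self.solver.dt,
            I_ext=self.I_ext,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; unknown keys are rejected with the
    offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, context=str(path))


def config_from_dict(raw: dict, context: str = "config") -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{context}: top level must be a mapping")
    data = dict(raw)
    sub = {}
    if "hazard" in data:
        sub["hazard"] = _strict_build(HazardSpec, data.pop("hazard"), f"{context}.hazard")
    if "solver" in data:
        sub["solver"] = _strict_build(SolverSpec, data.pop("solver"), f"{context}.solver")
    if "coupling" in data and data["coupling"] is not None:
        sub["coupling"] = _strict_build(
            CouplingSpec, data.pop("coupling"), f"{context}.coupling"
        )
    cfg = _strict_build(RunConfig, data, context)
    for k, v in sub.items():
        setattr(cfg, k, v)
    # surface validation errors from nested specs early
    cfg.build_hazard()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    if cfg.coupling is None:
        data.pop("coupling")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _fig3_like(**over) -> dict:
    base = dict(
        hazard=HazardSpec("exp_relax", {"t_ref": 10.0, "tau": 5.0}),
        I_ext=2.0,
        J_s=15.0,
        tau_s=10.0,
        N=5000,
        solver=SolverSpec(dt=0.05),
    )
    base.update(over)
    return base


FIXTURES = {
    # recurrent excitatory network, oscillatory regime
    "fig1": lambda: RunConfig(**_fig3_like()),
    # tau = 0 (hard threshold): steady state and bifurcation studies;
    # the asynchronous/oscillatory marker points are package choices of
    # representative coordinates on either side of the boundary
    "fig2": lambda: RunConfig(
        hazard=HazardSpec("exp_relax", {"t_ref": 8.0, "tau": 0.0}),
        I_ext=2.0,
        J_s=1.0,
        tau_s=10.0,
        N=5000,
        solver=SolverSpec(dt=0.1),
        extras={"async_point": {"I_ext": 0.5, "J_s": 2.0},
                "osc_point": {"I_ext": 2.0, "J_s": 15.0}},
    ),
    # the mPRC reference case
    "fig3": lambda: RunConfig(**_fig3_like()),
    # alternative single-cell descriptions (hazard families)
    "fig4a": lambda: RunConfig(
        hazard=HazardSpec("ramp", {"t_ref": 6.0, "eps": 3.0}),
        I_ext=2.5, J_s=4.0, tau_s=10.0, N=5000, solver=SolverSpec(dt=0.05),
    ),
    "fig4b": lambda: RunConfig(
        hazard=HazardSpec("tanh", {"t_ref": 5.0}),
        I_ext=2.5, J_s=3.0, tau_s=10.0, N=5000, solver=SolverSpec(dt=0.05),
    ),
    "fig4c": lambda: RunConfig(
        hazard=HazardSpec("tanh_cos", {"t_ref": 10.0, "eps": 3.0, "omega": 1.0}),
        I_ext=2.5, J_s=15.0, tau_s=3.0, N=5000, solver=SolverSpec(dt=0.05),
    ),
    # two delay-coupled circuits
    "fig5": lambda: RunConfig(
        **_fig3_like(solver=SolverSpec(dt=0.005)),
        coupling=CouplingSpec(G_s=0.2, eps=1.0, d=0.5),
        extras={"delays": [0.5, 2.5, 4.5]},
    ),
}


def make_fixture(name: str) -> RunConfig:
    """Named parameter sets for the standard study conditions."""
    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return FIXTURES[name]()
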