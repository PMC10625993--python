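"""Case presets, configuration handling and run orchestration.

Presets reproduce the canonical verification cases with their published
parameters:

* ``pipe3d``   — steady flow in a straight pipe (CGS units): R = 1 cm,
  L = 15 cm, parabolic inlet with Q = 10 mL/s, mu = 1 g/(cm s); densities
  1.571 / 15.71 / 157.1 g/mL give Re = 10 / 100 / 1000.  Verified against
  the Hagen-Poiseuille pressure drop.
* ``channel2d`` — 2D plane-channel analogue (nondimensional units):
  H = 1, L = 3, mean inlet speed 1, nu = 0.01 (Re = 100), verified against
  the plane-Poiseuille pressure drop 12 mu L U_mean / H^2.
* ``square2d`` — external flow over a 1 m square in a 29.2 m x 12 m box
  (SI units): uniform inlet 51.3 m/s, rho = 1.18e-3 kg/m^3,
  mu = 1.82e-4 kg/(m s) (Re = 332); vortex shedding statistics.
* ``square2d_re22000`` — same geometry with mu = 2.75e-6 kg/(m s).
* ``mms`` — unsteady manufactured solution on the unit square for
  convergence-order measurement.

Every preset has a coarse ``desk`` scale (used by the test suite) and a
finer ``paper`` scale; both are fully self-contained.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .assembly import (AssemblyContext, BCSet, DirichletBC, FluidProperties,
                       State, mms_forcing, parabolic_inlet_profile)
from .mesh import Mesh, generate_channel_mesh_2d, generate_obstacle_mesh_2d, \
    generate_pipe_mesh_3d
from .postprocess import ForceSeries, bulk_statistics, poiseuille_reference, \
    pressure_drop, surface_force
from .stabilization import l2_norm_field
from .timeint import SolverConfig, run_transient, solve_steady

__all__ = ["CaseConfig", "CaseSetup", "load_config", "build_case",
           "run_case", "PRESETS", "render_table"]

PRESETS = ("pipe3d", "channel2d", "square2d", "square2d_re22000", "mms")

# density (g/mL) giving each pipe Reynolds number at Q = 10 mL/s, mu = 1
PIPE_DENSITY_BY_RE = {10: 1.571, 100: 15.71, 1000: 157.1}

_KNOWN_KEYS = {"preset", "scale", "formulation", "dt", "t_end", "Re", "out",
               "mode", "window", "rho_inf", "newton_drop_orders",
               "linear_tol", "store_fields", "refinements", "n_steps"}


@dataclass
class CaseConfig:
    """Fully resolved case configuration (every default explicit)."""

    preset: str
    scale: str = "desk"
    formulation: str = "present"
    dt: float | None = None
    t_end: float | None = None
    Re: float | None = None
    mode: str | None = None  # steady | transient (preset default otherwise)
    window: tuple[float, float] | None = None
    rho_inf: float = 0.5
    newton_drop_orders: float | None = None
    linear_tol: float = 1e-2
    out: str | None = None
    store_fields: bool = False
    refinements: int = 3  # mms only
    n_steps: int | None = None

    def resolved(self) -> dict:
        return asdict(self)


@dataclass
class CaseSetup:
    """Assembled ingredients of a run."""

    mesh: Mesh
    ctx: AssemblyContext
    props: FluidProperties
    bcs: BCSet
    cfg: SolverConfig
    reference: dict = field(default_factory=dict)


def load_config(source, overrides: dict | None = None) -> CaseConfig:
    """Resolve a preset name or a YAML/JSON config file into a CaseConfig.

    Unknown keys, missing required values or inconsistent settings raise a
    ValueError naming the offending field.
    """
    data: dict
    if isinstance(source, str) and source in PRESETS:
        data = {"preset": source}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        import yaml
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    data.update(overrides or {})
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "preset" not in data:
        raise ValueError("config error: required fields missing: ['preset'] "
                         f"(known keys: {sorted(_KNOWN_KEYS)})")
    if data["preset"] not in PRESETS:
        raise ValueError(f"unknown preset {data['preset']!r}; "
                         f"choose from {PRESETS}")
    cfg = CaseConfig(**data)
    if cfg.scale not in ("desk", "paper"):
        raise ValueError("scale must be 'desk' or 'paper'")
    if cfg.formulation not in ("conventional", "present"):
        raise ValueError("formulation must be 'conventional' or 'present'")
    if cfg.preset == "pipe3d":
        if cfg.Re is None:
            cfg.Re = 1000
        if int(cfg.Re) not in PIPE_DENSITY_BY_RE:
            raise ValueError("pipe3d Re must be one of 10, 100, 1000")
    return cfg


def build_case(cfg: CaseConfig) -> CaseSetup:
    """Construct mesh, fluid, boundary conditions and solver settings."""
    if cfg.preset == "pipe3d":
        return _build_pipe(cfg)
    if cfg.preset == "channel2d":
        return _build_channel(cfg)
    if cfg.preset in ("square2d", "square2d_re22000"):
        return _build_square(cfg)
    if cfg.preset == "mms":
        return _build_mms(cfg, n=8)
    raise ValueError(cfg.preset)


def _solver_config(cfg: CaseConfig, default_dt, default_t_end,
                   drop=3.0) -> SolverConfig:
    return SolverConfig(
        dt=cfg.dt if cfg.dt is not None else default_dt,
        t_end=cfg.t_end if cfg.t_end is not None else default_t_end,
        rho_inf=cfg.rho_inf,
        formulation=cfg.formulation,
        newton_drop_orders=(cfg.newton_drop_orders
                            if cfg.newton_drop_orders is not None else drop),
        linear_tol=cfg.linear_tol)


def _build_pipe(cfg: CaseConfig) -> CaseSetup:
    R, L, Q, mu = 1.0, 15.0, 10.0, 1.0
    rho = PIPE_DENSITY_BY_RE[int(cfg.Re)]
    if cfg.scale == "desk":
        mesh = generate_pipe_mesh_3d(R, L, target_h=0.25, axial_h=0.2,
                                     perturb=0.12)
    else:
        mesh = generate_pipe_mesh_3d(R, L, target_h=0.1, axial_h=0.1,
                                     perturb=0.12)
    props = FluidProperties(rho=rho, mu=mu)
    inflow = parabolic_inlet_profile(mesh, "inlet", Q, pipe_radius=R)
    bcs = BCSet(dirichlet=[DirichletBC("inlet", (0, 1, 2), inflow),
                           DirichletBC("wall", (0, 1, 2), 0.0)])
    sol = _solver_config(cfg, 1e-4, 5.0, drop=3.5)
    ref = poiseuille_reference(Q, R, L, mu, rho, dt=sol.dt, mesh=mesh)
    return CaseSetup(mesh, AssemblyContext(mesh), props, bcs, sol,
                     {"poiseuille": ref, "Q": Q, "R": R, "L": L})


def _build_channel(cfg: CaseConfig) -> CaseSetup:
    L, H, u_mean = 3.0, 1.0, 1.0
    rho, mu = 1.0, 0.01  # Re = u_mean H / nu = 100
    if cfg.scale == "desk":
        nx, ny = 36, 12
    else:
        nx, ny = 90, 30
    mesh = generate_channel_mesh_2d(L, H, nx, ny, perturb=0.2)
    props = FluidProperties(rho=rho, mu=mu)
    inflow = parabolic_inlet_profile(mesh, "inlet", u_mean * H,
                                     channel_height=H)
    bcs = BCSet(dirichlet=[DirichletBC("inlet", (0, 1), inflow),
                           DirichletBC("wall_bottom", (0, 1), 0.0),
                           DirichletBC("wall_top", (0, 1), 0.0)])
    sol = _solver_config(cfg, 1e-3, 5.0)
    dp_ref = 12.0 * mu * L * u_mean / H**2  # plane Poiseuille
    return CaseSetup(mesh, AssemblyContext(mesh), props, bcs, sol,
                     {"dp_ref": dp_ref, "L": L, "H": H, "u_mean": u_mean})


def _build_square(cfg: CaseConfig) -> CaseSetup:
    U, D = 51.3, 1.0
    rho = 1.18e-3
    mu = 2.75e-6 if cfg.preset == "square2d_re22000" else 1.82e-4
    if cfg.scale == "desk":
        # near-square h = D/12 with rapid geometric coarsening: the same
        # grading philosophy as the full-resolution mesh, scaled down
        mesh = generate_obstacle_mesh_2d(target_h=0.0833, growth=1.3,
                                         h_max=2.0)
    else:
        mesh = generate_obstacle_mesh_2d(target_h=0.025, h_max=0.35)
    props = FluidProperties(rho=rho, mu=mu)
    bcs = BCSet(dirichlet=[
        DirichletBC("inlet", (0, 1), np.array([U, 0.0])),
        DirichletBC("obstacle", (0, 1), 0.0),
        # no-penetration walls: u_y = 0, zero traction in x
        DirichletBC("wall_bottom", (1,), 0.0),
        DirichletBC("wall_top", (1,), 0.0),
    ])
    default_dt = 5e-3 if cfg.preset == "square2d_re22000" else \
        (4e-3 if cfg.scale == "desk" else 1e-3)
    sol = _solver_config(cfg, default_dt, 5.0)
    # bluff-body runs: impulsive start needs the dt ramp and the extended
    # omega = 2/dt fallback until the starting vortex has formed (~0.6 s)
    sol.ramp_steps = 10
    sol.ramp_start_dt = max(sol.dt, 2e-2)
    sol.omega_fallback_steps = int(round(0.6 / sol.dt))
    sol.tangent_refresh = "step"
    sol.precond_refresh_steps = 5
    sol.newton_max_iters = 40
    return CaseSetup(mesh, AssemblyContext(mesh), props, bcs, sol,
                     {"U_ref": U, "D_ref": D, "rho_ref": rho,
                      "Re": rho * U * D / mu})


def _build_mms(cfg: CaseConfig, n: int) -> CaseSetup:
    import sympy as sm
    x, y, t = sm.symbols("x y t")
    rho, mu = 1.0, 0.1
    props = FluidProperties(rho=rho, mu=mu)
    u_exprs = (sm.sin(t) * y * (1 - y), sm.Integer(0))
    p_expr = sm.Integer(0)
    f_fn, u_fn, p_fn = mms_forcing(u_exprs, p_expr, props, coords=(x, y))
    mesh = generate_channel_mesh_2d(1.0, 1.0, n, n)
    bcs = BCSet(
        dirichlet=[DirichletBC(name, (0, 1),
                               lambda c, tt, fn=u_fn: fn(c, tt))
                   for name in ("inlet", "outlet", "wall_bottom", "wall_top")],
        body_force=f_fn, pin_pressure_node=0)
    for name in mesh.boundary_patches:
        mesh.boundary_patches[name].role = "dirichlet"
    sol = _solver_config(cfg, 5e-3, 0.25)
    return CaseSetup(mesh, AssemblyContext(mesh), props, bcs, sol,
                     {"u_exact": u_fn, "p_exact": p_fn})


# ---------------------------------------------------------------------------
# orchestration


def run_case(cfg: CaseConfig) -> dict:
    """Execute a preset end to end and return a machine-readable report.

    Steady presets (pipe3d, channel2d) solve the dt-dependent steady
    problem of the requested formulation and report dP/dP_ref; square2d
    runs the transient with force/omega logging and reports shedding
    statistics; mms runs the refinement study and reports the observed
    convergence order.
    """
    report: dict = {"config": cfg.resolved()}
    if cfg.preset == "mms":
        report.update(run_mms_convergence(cfg))
    elif cfg.preset in ("pipe3d", "channel2d"):
        setup = build_case(cfg)
        mode = cfg.mode or "steady"
        if mode == "steady":
            state = solve_steady(setup.ctx, setup.props, setup.bcs, setup.cfg)
        else:
            state, diags, _ = run_transient(State.zero(setup.mesh), setup.cfg,
                                            setup.ctx, setup.props, setup.bcs)
            report["diagnostics"] = diags.to_dict("list")
        dp = pressure_drop(state, setup.mesh)
        dp_ref = (setup.reference["poiseuille"].dP_ref
                  if cfg.preset == "pipe3d" else setup.reference["dp_ref"])
        report.update({"dP": dp, "dP_ref": dp_ref, "dP_ratio": dp / dp_ref,
                       "n_el": setup.mesh.n_el})
        report["_state"] = state
        report["_setup"] = setup
    else:
        setup = build_case(cfg)
        out = run_square_transient(setup, cfg)
        report.update(out)
    if cfg.out:
        _write_outputs(report, cfg)
    return report


def run_square_transient(setup: CaseSetup, cfg: CaseConfig,
                         initial: State | None = None,
                         omega_state=None, step_offset: int = 0) -> dict:
    """Transient bluff-body run with per-step force and omega logging."""
    rows = []
    ref = setup.reference

    def cb(state, diag):
        fd, fl = surface_force(setup.ctx, state, "obstacle", setup.props,
                               setup.bcs, setup.cfg.stabilization(),
                               omega=diag.omega)
        rows.append((state.t, fd, fl))

    init = initial if initial is not None else State.zero(setup.mesh)
    n_steps = cfg.n_steps
    state, diags, om = run_transient(init, setup.cfg, setup.ctx, setup.props,
                                     setup.bcs, omega_state=omega_state,
                                     n_steps=n_steps,
                                     step_offset=step_offset, callback=cb)
    series = ForceSeries(*(np.array(c) for c in zip(*rows)))
    out = {"series": series, "diagnostics": diags, "omega_state": om,
           "_state": state, "_setup": setup, "n_el": setup.mesh.n_el}
    window = cfg.window
    if window is None:
        # stationary window: discard the first 60% of the run
        t1 = float(series.times[-1])
        window = (0.6 * t1, t1)
    stats = bulk_statistics(series, window, ref["U_ref"], ref["D_ref"],
                            ref["rho_ref"], integer_periods=True)
    sel = (diags["t"] >= window[0]) & (diags["t"] <= window[1])
    out["stats"] = stats
    out["omega_mean"] = float(diags.loc[sel, "omega"].mean())
    return out


def run_mms_convergence(cfg: CaseConfig) -> dict:
    """Velocity L2 convergence under uniform refinement for the unsteady
    manufactured solution; returns errors and the observed order."""
    errors, hs = [], []
    n0 = 8
    for lev in range(cfg.refinements):
        n = n0 * 2**lev
        setup = _build_mms(cfg, n=n)
        state, _, _ = run_transient(State.zero(setup.mesh), setup.cfg,
                                    setup.ctx, setup.props, setup.bcs)
        u_ex = setup.reference["u_exact"](setup.mesh.nodes, state.t)
        err = l2_norm_field(state.u - u_ex, setup.mesh)
        errors.append(err)
        hs.append(1.0 / n)
    orders = [float(np.log(errors[i] / errors[i + 1]) / np.log(2.0))
              for i in range(len(errors) - 1)]
    fit = float(np.polyfit(np.log(hs), np.log(errors), 1)[0])
    return {"h": hs, "velocity_l2_errors": errors, "orders": orders,
            "observed_order": fit}


def render_table(stats_by_run: dict[str, dict]) -> pd.DataFrame:
    """Render bulk-statistics rows (one per run label) in the layout of the
    benchmark comparison tables."""
    cols = ["Cd_mean", "Cd_rms_fluct", "Cl_mean", "Cl_rms_fluct", "St"]
    rows = {label: {c: d.get(c, float("nan")) for c in cols}
            for label, d in stats_by_run.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("tcflow")
    except PackageNotFoundError:
        return "unknown"


def _write_outputs(report: dict, cfg: CaseConfig) -> None:
    from .io import write_fields

    os.makedirs(cfg.out, exist_ok=True)
    resolved = {"tcflow_version": _version(), **cfg.resolved()}
    with open(os.path.join(cfg.out, "config.json"), "w") as fh:
        json.dump(resolved, fh, indent=2)
    clean = {}
    for k, v in report.items():
        if k.startswith("_") or k in ("series", "diagnostics", "omega_state"):
            continue
        clean[k] = v.as_dict() if hasattr(v, "as_dict") else v
    with open(os.path.join(cfg.out, "report.json"), "w") as fh:
        json.dump(clean, fh, indent=2, default=float)
    if isinstance(report.get("diagnostics"), pd.DataFrame):
        report["diagnostics"].to_csv(
            os.path.join(cfg.out, "diagnostics.csv"), index=False)
    if "series" in report:
        s = report["series"]
        pd.DataFrame({"t": s.times, "F_D": s.F_D, "F_L": s.F_L}).to_csv(
            os.path.join(cfg.out, "forces.csv"), index=False)
    if "omega_state" in report:
        hist = report["omega_state"].history
        df = pd.DataFrame(hist, columns=["t", "omega"])
        df["formulation"] = cfg.formulation
        df.to_csv(os.path.join(cfg.out, "omega.csv"), index=False)
    if cfg.store_fields and "_state" in report:
        write_fields(report["_setup"].mesh, report["_state"],
                     os.path.join(cfg.out, "fields.vtu"))
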