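"""Implicit generalized-alpha time integration with Newton-Krylov solves.

The coupled velocity-pressure system is advanced with the generalized-alpha
method for first-order systems (spectral radius rho_inf controls
high-frequency damping; rho_inf = 1 recovers the midpoint rule).  Each step
performs Newton-Raphson iterations on the intermediate-time residual until
its l2 norm drops by a configured number of orders of magnitude, solving the
(frozen-tau) tangent system with restarted GMRES preconditioned by an
incomplete LU factorization.

The global flow frequency omega is updated once per step from the previous
step's converged state and held fixed within the Newton loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from .assembly import AssemblyContext, BCSet, FluidProperties, State, \
    assemble_residual, assemble_tangent
from .stabilization import OmegaState, StabilizationSettings, omega_global

__all__ = [
    "GeneralizedAlphaParams",
    "genalpha_coefficients",
    "SolverConfig",
    "StepFailure",
    "StepDiagnostics",
    "advance_step",
    "run_transient",
    "solve_steady",
    "genalpha_ode_solve",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneralizedAlphaParams:
    """Coefficients of the first-order generalized-alpha scheme."""

    rho_inf: float
    alpha_m: float
    alpha_f: float
    gamma: float


def genalpha_coefficients(rho_inf: float) -> GeneralizedAlphaParams:
    """alpha_m = (3 - rho_inf)/(2 (1 + rho_inf)), alpha_f = 1/(1 + rho_inf),
    gamma = 1/2 + alpha_m - alpha_f (second-order accuracy identity)."""
    if not 0.0 <= rho_inf <= 1.0:
        raise ValueError("rho_inf must lie in [0, 1]")
    alpha_m = 0.5 * (3.0 - rho_inf) / (1.0 + rho_inf)
    alpha_f = 1.0 / (1.0 + rho_inf)
    gamma = 0.5 + alpha_m - alpha_f
    return GeneralizedAlphaParams(rho_inf, alpha_m, alpha_f, gamma)


@dataclass
class SolverConfig:
    """Time integrator, Newton and linear-solver settings."""

    dt: float = 1e-3
    t_end: float = 1.0
    rho_inf: float = 0.5
    formulation: str = "present"  # stabilization choice
    C_I: float = 3.0
    epsilon_u: float = 1e-14
    newton_drop_orders: float = 3.0
    newton_max_iters: int = 25
    newton_abs_floor: float = 1e-12
    linear_solver: str = "gmres"  # gmres | direct
    linear_tol: float = 1e-2
    linear_restart: int = 200
    linear_maxiter: int = 2000
    ilu_drop_tol: float = 1e-5
    ilu_fill_factor: float = 30.0
    tangent_refresh: str = "iter"  # iter: full Newton; step: modified Newton
    precond: str = "lu"  # lu | ilu factorization used as GMRES preconditioner
    # steps between preconditioner refactorizations; the tangent itself is
    # always current, so a stale factorization only costs Krylov iterations
    precond_refresh_steps: int = 1
    ramp_steps: int = 0  # optional geometric start-up ramp of dt
    ramp_start_dt: float | None = None
    # extend the first-step omega = 2/dt fallback over a start-up window:
    # impulsively started flows have large accelerations in regions of
    # near-zero velocity, where an omega-based tau is locally enormous
    omega_fallback_steps: int = 0
    stop_on_steady: bool = False
    steady_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.linear_tol < 1.0:
            raise ValueError("linear_tol must lie in (0, 1)")

    def stabilization(self, dt: float | None = None) -> StabilizationSettings:
        return StabilizationSettings(self.formulation, self.C_I,
                                     dt if dt is not None else self.dt,
                                     self.epsilon_u)


class StepFailure(RuntimeError):
    """Raised when a time step fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class StepDiagnostics:
    step: int
    t: float
    dt: float
    omega: float
    newton_iters: int
    linear_iters: int
    residual_ratio: float
    converged: bool


class _LinearSolver:
    """Preconditioned GMRES (or direct) solve of the tangent system.

    The operator is always the current tangent; the preconditioner (exact or
    incomplete LU) may be reused for ``precond_refresh_steps`` steps — a
    stale preconditioner costs Krylov iterations, never accuracy.  Inner
    iterations are counted for the solver-cost diagnostics.
    """

    def __init__(self, cfg: SolverConfig):
        self.cfg = cfg
        self.iters = 0
        self._factor_step = None
        self._M = None

    def set_system(self, A, step: int, force_factor: bool = False) -> None:
        self._A = A
        stale = (self._factor_step is None or force_factor
                 or step - self._factor_step >= self.cfg.precond_refresh_steps)
        if self.cfg.linear_solver == "direct":
            if stale or True:  # direct mode always factors the current matrix
                self._op = spla.splu(A.tocsc())
                self._factor_step = step
            return
        if stale:
            if self.cfg.precond == "ilu":
                fac = spla.spilu(A.tocsc(), drop_tol=self.cfg.ilu_drop_tol,
                                 fill_factor=self.cfg.ilu_fill_factor)
            else:
                fac = spla.splu(A.tocsc())
            self._M = spla.LinearOperator(A.shape, fac.solve)
            self._factor_step = step

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.cfg.linear_solver == "direct":
            self.iters += 1
            return self._op.solve(b)
        count = [0]

        def cb(_):
            count[0] += 1

        outer = max(1, math.ceil(self.cfg.linear_maxiter
                                 / self.cfg.linear_restart))
        x, info = spla.gmres(self._A, b, rtol=self.cfg.linear_tol, atol=0.0,
                             restart=self.cfg.linear_restart, maxiter=outer,
                             M=self._M, callback=cb,
                             callback_type="pr_norm")
        self.iters += count[0]
        if info > 0:
            # ILU-preconditioned GMRES can stall on the stiffest cold-start
            # systems; fall back to a direct factorization of this tangent.
            x = spla.splu(self._A.tocsc()).solve(b)
        return x


def _apply_dirichlet_state(u, a, u_n, a_n, dofs, values, gamma, dt):
    """Impose u_{n+1} = g on constrained dofs and make the acceleration
    consistent with the generalized-alpha update relation."""
    d = u.shape[1]
    node, comp = dofs // (d + 1), dofs % (d + 1)
    u[node, comp] = values
    a[node, comp] = (u[node, comp] - u_n[node, comp]) / (gamma * dt) \
        + (gamma - 1.0) / gamma * a_n[node, comp]


def advance_step(state_n: State, cfg: SolverConfig, ctx: AssemblyContext,
                 props: FluidProperties, bcs: BCSet,
                 settings: StabilizationSettings, omega: float,
                 alpha: GeneralizedAlphaParams | None = None,
                 dt: float | None = None,
                 step_index: int = 0,
                 lin: "_LinearSolver | None" = None
                 ) -> tuple[State, StepDiagnostics]:
    """Advance one time step; omega must already be updated for this step.

    Predictor: same velocity, scaled acceleration a0 = ((gamma-1)/gamma) a_n.
    Newton unknowns are the acceleration increment and the pressure; the
    velocity follows via u += gamma dt da.  Convergence is measured on the
    true assembled residual.
    """
    if alpha is None:
        alpha = genalpha_coefficients(cfg.rho_inf)
    if dt is None:
        dt = cfg.dt
    am, af, gamma = alpha.alpha_m, alpha.alpha_f, alpha.gamma
    d = ctx.dim
    t_np1 = state_n.t + dt
    t_int = state_n.t + af * dt

    u1 = state_n.u.copy()
    a1 = (gamma - 1.0) / gamma * state_n.a
    p1 = state_n.p.copy()
    cdofs, cvals = bcs.constrained(ctx.mesh, t_np1)
    _apply_dirichlet_state(u1, a1, state_n.u, state_n.a, cdofs, cvals,
                           gamma, dt)

    if lin is None:
        lin = _LinearSolver(cfg)
    lin0 = lin.iters

    def residual(u_np1, a_np1, p_np1):
        u_int = state_n.u + af * (u_np1 - state_n.u)
        a_int = state_n.a + am * (a_np1 - state_n.a)
        return assemble_residual(ctx, props, u_int, p_np1, a_int,
                                 t_int, bcs, settings, omega), u_int, a_int

    R, u_int, a_int = residual(u1, a1, p1)
    norm = r0 = float(np.linalg.norm(R))
    n_eval = 1
    converged = False
    tol = max(r0 * 10.0 ** (-cfg.newton_drop_orders), cfg.newton_abs_floor)
    contraction = 0.0
    for it in range(cfg.newton_max_iters):
        if norm <= tol:
            converged = True
            break
        # modified Newton ("step") keeps the first factorization unless the
        # residual contraction degrades; full Newton ("iter") refreshes always
        if it == 0 or cfg.tangent_refresh == "iter" or contraction > 0.2:
            K = assemble_tangent(ctx, props, u_int, p1, a_int, t_int, bcs,
                                 settings, omega, c_u=af * gamma * dt,
                                 c_a=am)
            lin.set_system(K, step_index, force_factor=contraction > 0.2)
        delta = lin.solve(-R).reshape(-1, d + 1)
        # backtracking line search on the true residual norm
        lam = 1.0
        for _ls in range(7):
            a_try = a1 + lam * delta[:, :d]
            u_try = u1 + lam * gamma * dt * delta[:, :d]
            p_try = p1 + lam * delta[:, d]
            R_try, ui_try, ai_try = residual(u_try, a_try, p_try)
            n_try = float(np.linalg.norm(R_try))
            n_eval += 1
            if n_try < norm or n_try <= tol:
                break
            lam *= 0.5
        u1, a1, p1 = u_try, a_try, p_try
        contraction = n_try / norm if norm > 0 else 0.0
        R, u_int, a_int, norm = R_try, ui_try, ai_try, n_try

    ratio = norm / r0 if r0 > 0 else 0.0
    diag = StepDiagnostics(step_index, t_np1, dt, omega, n_eval,
                           lin.iters - lin0, ratio, converged)
    if not converged:
        raise StepFailure(
            f"Newton failed at t={t_np1:.6g} (residual ratio {ratio:.3e})",
            diag)
    return State(u1, p1, a1, t_np1), diag


def run_transient(initial: State, cfg: SolverConfig, ctx: AssemblyContext,
                  props: FluidProperties, bcs: BCSet,
                  omega_state: OmegaState | None = None,
                  n_steps: int | None = None,
                  step_offset: int = 0,
                  callback=None,
                  force_omega_2_over_dt: bool = False):
    """March the solution from ``initial`` to ``cfg.t_end``.

    Per step: (1) update omega from the previous step's state (first step
    and quiescent fields fall back to 2/dt), (2) advance with Newton-Krylov,
    (3) log omega and solver diagnostics.  For the conventional formulation
    omega is still computed and logged as a diagnostic, but tau uses 2/dt.

    Returns (final state, diagnostics DataFrame, omega_state).  ``callback``
    receives (state, diagnostics) after every step.  The run is
    deterministic: identical inputs give bitwise-identical trajectories.
    """
    alpha = genalpha_coefficients(cfg.rho_inf)
    if omega_state is None:
        omega_state = OmegaState()
    lin = _LinearSolver(cfg)
    state = initial.copy()
    if n_steps is None:
        n_steps = int(round((cfg.t_end - initial.t) / cfg.dt))
    rows = []
    ramp0 = cfg.ramp_start_dt if cfg.ramp_start_dt is not None else cfg.dt
    for k in range(n_steps):
        step = step_offset + k
        if cfg.ramp_steps > 0 and step < cfg.ramp_steps:
            frac = step / cfg.ramp_steps
            dt = ramp0 * (cfg.dt / ramp0) ** frac
        else:
            dt = cfg.dt
        settings = cfg.stabilization(dt)
        first = omega_state.is_first_step
        om = omega_global(state.u, state.a, ctx.mesh, settings,
                          is_first_step=first)
        if force_omega_2_over_dt or step < cfg.omega_fallback_steps:
            om = 2.0 / dt
        omega_state.update(state.t + dt, om)
        tau_omega = om if cfg.formulation == "present" else 2.0 / dt
        state, diag = advance_step(state, cfg, ctx, props, bcs, settings,
                                   tau_omega, alpha, dt=dt, step_index=step,
                                   lin=lin)
        rows.append((step, diag.t, diag.dt, om, diag.newton_iters,
                     diag.linear_iters, diag.residual_ratio))
        if callback is not None:
            callback(state, diag)
        if cfg.stop_on_steady and k > 0:
            du = np.linalg.norm(state.u - prev_u)
            if du <= cfg.steady_tol * max(1.0, np.linalg.norm(state.u)):
                break
        prev_u = state.u.copy()
    diags = pd.DataFrame(rows, columns=["step", "t", "dt", "omega",
                                        "newton_iters", "linear_iters",
                                        "residual_ratio"])
    return state, diags, omega_state


def solve_steady(ctx: AssemblyContext, props: FluidProperties, bcs: BCSet,
                 cfg: SolverConfig, omega: float = 0.0,
                 initial: State | None = None,
                 tol_rel: float = 1e-9, max_iters: int = 40) -> State:
    """Newton solve of the steady stabilized equations (a = 0).

    This is the fixed point of the generalized-alpha transient: at steady
    state the discrete acceleration vanishes and tau keeps its formulation's
    transient term (2/dt for the conventional one, omega — zero in steady
    flow — for the present one), which is exactly the mechanism that makes
    the conventional steady solution depend on dt.

    Uses a direct sparse factorization and backtracking line search.
    """
    settings = cfg.stabilization()
    mesh = ctx.mesh
    d = ctx.dim
    state = initial.copy() if initial is not None else State.zero(mesh)
    a0 = np.zeros_like(state.u)
    cdofs, cvals = bcs.constrained(mesh, 0.0)
    node, comp = cdofs // (d + 1), cdofs % (d + 1)
    state.u[node, comp] = cvals

    def resid(u, p):
        return assemble_residual(ctx, props, u, p, a0, 0.0, bcs, settings,
                                 omega)

    R = resid(state.u, state.p)
    norm0 = norm = float(np.linalg.norm(R))
    floor = 1e-12
    for _ in range(max_iters):
        if norm <= max(tol_rel * max(norm0, 1.0), floor):
            return state
        K = assemble_tangent(ctx, props, state.u, state.p, a0, 0.0, bcs,
                             settings, omega, c_u=1.0, c_a=0.0)
        delta = spla.splu(K.tocsc()).solve(-R).reshape(-1, d + 1)
        lam = 1.0
        for _ls in range(10):
            u_try = state.u + lam * delta[:, :d]
            p_try = state.p + lam * delta[:, d]
            R_try = resid(u_try, p_try)
            n_try = float(np.linalg.norm(R_try))
            if n_try < norm or n_try <= floor:
                break
            lam *= 0.5
        state.u, state.p, R, norm = u_try, p_try, R_try, n_try
    raise StepFailure(f"steady Newton stalled at residual {norm:.3e} "
                      f"(started {norm0:.3e})")


# ---------------------------------------------------------------------------
# generic generalized-alpha ODE driver (scheme-order reference)


def genalpha_ode_solve(f, dfdu, u0, dt: float, n_steps: int,
                       rho_inf: float = 0.5, newton_tol: float = 1e-12):
    """Integrate u' = f(u) with the same generalized-alpha update relations
    and predictor used by the flow solver.  Returns the trajectory array
    (n_steps + 1, len(u0)).  Used to verify the scheme's second-order
    accuracy independently of any mesh."""
    p = genalpha_coefficients(rho_inf)
    u = np.atleast_1d(np.asarray(u0, dtype=np.float64))
    a = np.atleast_1d(np.asarray(f(u), dtype=np.float64))  # consistent start
    out = [u.copy()]
    for _ in range(n_steps):
        u1 = u.copy()
        a1 = (p.gamma - 1.0) / p.gamma * a
        for _it in range(50):
            u_int = u + p.alpha_f * (u1 - u)
            a_int = a + p.alpha_m * (a1 - a)
            r = a_int - f(u_int)
            if np.linalg.norm(r) <= newton_tol:
                break
            jac = p.alpha_m * np.eye(u.size) \
                - p.alpha_f * p.gamma * dt * np.atleast_2d(dfdu(u_int))
            da = np.linalg.solve(jac, -r)
            a1 = a1 + da
            u1 = u1 + p.gamma * dt * da
        u, a = u1, a1
        out.append(u.copy())
    return np.array(out)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, state: State, omega_state: OmegaState,
                    step: int) -> None:
    """Write (u, p, a, t, omega history) to a .npz container."""
    hist = np.asarray(omega_state.history, dtype=np.float64).reshape(-1, 2)
    np.savez(path, u=state.u, p=state.p, a=state.a, t=state.t,
             omega=omega_state.omega, history=hist, step=step,
             is_first_step=omega_state.is_first_step)


def load_checkpoint(path) -> tuple[State, OmegaState, int]:
    z = np.load(path)
    state = State(z["u"], z["p"], z["a"], float(z["t"]))
    om = OmegaState(float(z["omega"]),
                    [tuple(r) for r in z["history"]],
                    bool(z["is_first_step"]))
    return state, om, int(z["step"])
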