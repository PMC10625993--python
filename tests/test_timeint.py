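import numpy as np
import pytest

from tcflow.assembly import (AssemblyContext, BCSet, DirichletBC,
                             FluidProperties, State, parabolic_inlet_profile)
from tcflow.mesh import generate_channel_mesh_2d
from tcflow.timeint import (SolverConfig, advance_step, genalpha_coefficients,
                            genalpha_ode_solve, load_checkpoint,
                            run_transient, save_checkpoint, solve_steady)


class TestGenAlphaCoefficients:
    def test_midpoint_limit(self):
        p = genalpha_coefficients(1.0)
        assert (p.alpha_m, p.alpha_f, p.gamma) == (0.5, 0.5, 0.5)

    def test_maximal_damping(self):
        p = genalpha_coefficients(0.0)
        assert (p.alpha_m, p.alpha_f, p.gamma) == (1.5, 1.0, 1.0)

    @pytest.mark.parametrize("rinf", [0.0, 0.2, 0.5, 0.83, 1.0])
    def test_second_order_identity(self, rinf):
        p = genalpha_coefficients(rinf)
        # exact up to one rounding ulp of the coefficient arithmetic
        assert abs(p.gamma - 0.5 - (p.alpha_m - p.alpha_f)) <= 2e-16

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            genalpha_coefficients(1.2)


def test_ode_second_order_convergence():
    """The generalized-alpha update relations integrate u' = -u with
    observed order 2 under dt halving."""
    errs = []
    for n in (20, 40, 80):
        traj = genalpha_ode_solve(lambda u: -u, lambda u: -np.eye(1),
                                  [1.0], dt=1.0 / n, n_steps=n, rho_inf=0.5)
        errs.append(abs(traj[-1, 0] - np.exp(-1.0)))
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert all(1.9 <= o <= 2.1 for o in orders)


def _small_channel():
    mesh = generate_channel_mesh_2d(3.0, 1.0, 12, 4, perturb=0.15)
    props = FluidProperties(1.0, 0.01)
    inflow = parabolic_inlet_profile(mesh, "inlet", 1.0, channel_height=1.0)
    bcs = BCSet(dirichlet=[DirichletBC("inlet", (0, 1), inflow),
                           DirichletBC("wall_bottom", (0, 1), 0.0),
                           DirichletBC("wall_top", (0, 1), 0.0)])
    return mesh, AssemblyContext(mesh), props, bcs


def test_zero_state_is_fixed_point():
    mesh = generate_channel_mesh_2d(1, 1, 3, 3)
    ctx = AssemblyContext(mesh)
    props = FluidProperties(1.0, 0.01)
    bcs = BCSet(dirichlet=[DirichletBC(nm, (0, 1), 0.0)
                           for nm in mesh.boundary_patches])
    cfg = SolverConfig(dt=0.1)
    state, diag = advance_step(State.zero(mesh), cfg, ctx, props, bcs,
                               cfg.stabilization(), omega=20.0)
    assert np.all(state.u == 0) and np.all(state.p == 0)
    assert diag.newton_iters == 1 and diag.converged


def test_steady_state_attractor():
    """The transient relaxes to a steady state with vanishing omega."""
    mesh, ctx, props, bcs = _small_channel()
    cfg = SolverConfig(dt=0.1, formulation="present", stop_on_steady=True,
                       steady_tol=1e-11)
    state, diags, om = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                                     n_steps=600)
    assert diags.shape[0] < 600  # steady detection triggered
    assert om.omega < 1e-8


def test_steady_solver_is_transient_fixed_point():
    """solve_steady computes the generalized-alpha fixed point: advancing
    one transient step from it leaves the state unchanged."""
    mesh, ctx, props, bcs = _small_channel()
    cfg = SolverConfig(dt=1e-3, formulation="conventional")
    st = solve_steady(ctx, props, bcs, cfg)
    nxt, diag = advance_step(st.copy(), cfg, ctx, props, bcs,
                             cfg.stabilization(), omega=2.0 / cfg.dt)
    assert np.linalg.norm(nxt.u - st.u) < 1e-8 * np.linalg.norm(st.u)


def test_formulation_equivalence_with_forced_omega():
    """present formulation with omega forced to 2/dt reproduces the
    conventional trajectory bitwise."""
    mesh, ctx, props, bcs = _small_channel()
    base = dict(dt=0.05, rho_inf=0.5, linear_solver="direct")
    s1, _, _ = run_transient(State.zero(mesh), SolverConfig(
        formulation="conventional", **base), ctx, props, bcs, n_steps=15)
    s2, _, _ = run_transient(State.zero(mesh), SolverConfig(
        formulation="present", **base), ctx, props, bcs, n_steps=15,
        force_omega_2_over_dt=True)
    assert np.array_equal(s1.u, s2.u) and np.array_equal(s1.p, s2.p)


def test_deterministic_rerun_bitwise():
    mesh, ctx, props, bcs = _small_channel()
    cfg = SolverConfig(dt=0.05, formulation="present")
    s1, _, _ = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                             n_steps=20)
    s2, _, _ = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                             n_steps=20)
    assert np.array_equal(s1.u, s2.u) and np.array_equal(s1.a, s2.a)


def test_checkpoint_restart_bitwise(tmp_path):
    mesh, ctx, props, bcs = _small_channel()
    cfg = SolverConfig(dt=0.05, formulation="present")
    full, _, _ = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                               n_steps=30)
    half, _, om = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                                n_steps=15)
    path = tmp_path / "chk.npz"
    save_checkpoint(path, half, om, step=15)
    st, om2, step = load_checkpoint(path)
    assert step == 15 and np.array_equal(st.u, half.u)
    resumed, _, _ = run_transient(st, cfg, ctx, props, bcs,
                                  omega_state=om2, n_steps=15,
                                  step_offset=15)
    assert np.array_equal(resumed.u, full.u)
    assert np.array_equal(resumed.p, full.p)
    assert np.array_equal(resumed.a, full.a)


def test_omega_history_decays_for_steady_case():
    """omega falls from the 2/dt start toward zero as the channel flow
    approaches steady state (the canonical decay history)."""
    mesh, ctx, props, bcs = _small_channel()
    cfg = SolverConfig(dt=0.1, formulation="present")
    _, diags, _ = run_transient(State.zero(mesh), cfg, ctx, props, bcs,
                                n_steps=100)
    om = diags["omega"].to_numpy()
    assert om[0] == 2.0 / cfg.dt
    # monotone decay after the initial transient
    tail = om[10:]
    assert np.all(np.diff(tail) <= 1e-12)
    assert tail[-1] < 1e-2 * tail[0]
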