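import numpy as np
import pytest
import sympy as sm

from tcflow.assembly import (AssemblyContext, BCSet, DirichletBC,
                             FluidProperties, NeumannBC, ShapeFunctionTable,
                             assemble_residual, assemble_tangent, mms_forcing,
                             parabolic_inlet_profile, strong_residuals)
from tcflow.mesh import (compute_metric_tensors, generate_channel_mesh_2d,
                         generate_pipe_mesh_3d, shape_gradients)
from tcflow.stabilization import (StabilizationSettings, nu_c,
                                  tau_supg_present)

PROPS = FluidProperties(rho=1.3, mu=0.02)


def test_shape_table_partition_of_unity():
    for d in (2, 3):
        tab = ShapeFunctionTable(d)
        assert np.allclose(tab.N.sum(axis=1), 1.0)
        assert np.allclose(tab.parent_gradients.sum(axis=0), 0.0)
        assert tab.weights.sum() == pytest.approx(1.0)


class TestStrongResiduals:
    def test_quiescent(self):
        rm, rc = strong_residuals(np.zeros(2), np.zeros((2, 2)), np.zeros(2),
                                  np.zeros(2), PROPS)
        assert np.allclose(rm, 0) and rc == 0

    def test_hand_calculus(self):
        # u = (x, -y): grad_u = [[1,0],[0,-1]], u.grad u = (x, y), div = 0
        x, y = 0.7, -0.3
        u = np.array([x, -y])
        grad_u = np.array([[1.0, 0.0], [0.0, -1.0]])
        rm, rc = strong_residuals(u, grad_u, np.zeros(2), np.zeros(2), PROPS)
        assert np.allclose(rm, PROPS.rho * np.array([x, y]))
        assert rc == pytest.approx(0.0)

    def test_forcing_cancellation(self):
        a = np.array([2.0, -1.0])
        rm, _ = strong_residuals(np.full(2, 3.0), np.zeros((2, 2)),
                                 np.zeros(2), a, PROPS, f_gp=a)
        assert np.allclose(rm, 0.0)


def _naive_residual(mesh, props, u, p, a, settings, omega, body=None):
    """Independent per-element quadrature assembly (pure loops)."""
    w_q, bary = ((np.full(3, 1 / 3),
                  np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6],
                            [1 / 6, 1 / 6, 2 / 3]])))
    d = mesh.dim
    nn = d + 1
    R = np.zeros(mesh.n_nodes * (d + 1))
    vol, grads = shape_gradients(mesh)
    G = compute_metric_tensors(mesh)
    for e, el in enumerate(mesh.elements):
        ue, pe, ae = u[el], p[el], a[el]
        gr = grads[e]
        grad_u = sum(np.outer(ue[b], gr[b]) for b in range(nn))
        grad_p = sum(pe[b] * gr[b] for b in range(nn))
        divu = np.trace(grad_u)
        xe = mesh.nodes[el]
        for g in range(3):
            N = bary[g]
            ug = N @ ue
            ag = N @ ae
            xg = N @ xe
            fg = body(xg) if body is not None else np.zeros(d)
            conv = grad_u @ ug
            rm = props.rho * (ag + conv - fg) + grad_p
            tau = tau_supg_present(omega, ug, G[e], props.nu, settings.C_I)
            nc = nu_c(G[e], tau)
            wv = w_q[g] * vol[e]
            for b in range(nn):
                dofv = el[b] * (d + 1)
                # Galerkin momentum
                R[dofv:dofv + d] += wv * N[b] * props.rho * (ag + conv - fg)
                # SUPG
                R[dofv:dofv + d] += wv * tau * (ug @ gr[b]) * rm
                # grad-div
                R[dofv:dofv + d] += wv * props.rho * nc * gr[b] * divu
                # PSPG + Galerkin continuity
                R[dofv + d] += wv * (tau / props.rho) * (gr[b] @ rm)
                R[dofv + d] += wv * divu * N[b]
        # stress term (integrand constant except p -> element mean)
        sig_visc = props.mu * (grad_u + grad_u.T)
        for b in range(nn):
            dofv = el[b] * (d + 1)
            R[dofv:dofv + d] += vol[e] * (sig_visc @ gr[b]
                                          - pe.mean() * gr[b])
    return R


def test_residual_matches_naive_oracle():
    mesh = generate_channel_mesh_2d(1, 1, 2, 1, perturb=0.2, seed=2)
    rng = np.random.default_rng(8)
    u = rng.normal(size=(mesh.n_nodes, 2))
    p = rng.normal(size=mesh.n_nodes)
    a = rng.normal(size=(mesh.n_nodes, 2))
    settings = StabilizationSettings("present", 3.0, 1e-2)
    omega = 4.0

    def body(x):
        return np.array([0.3 * x[0] - x[1], 1.0 + x[1]])

    bcs = BCSet(body_force=lambda x, t: np.stack(
        [0.3 * x[..., 0] - x[..., 1], 1.0 + x[..., 1]], axis=-1))
    R = assemble_residual(AssemblyContext(mesh), PROPS, u, p, a, 0.0, bcs,
                          settings, omega, apply_bc=False)
    R_naive = _naive_residual(mesh, PROPS, u, p, a, settings, omega, body)
    scale = np.abs(R_naive).max()
    assert np.abs(R - R_naive).max() < 1e-12 * scale


@pytest.mark.parametrize("dim", [2, 3])
def test_tangent_matches_finite_difference(dim):
    """Matrix-vector products of the consistent tangent agree with finite
    differences of the full residual (tau linearization included)."""
    if dim == 2:
        mesh = generate_channel_mesh_2d(1, 1, 3, 3, perturb=0.15)
    else:
        mesh = generate_pipe_mesh_3d(1.0, 3.0, 0.5, axial_h=1.0)
    ctx = AssemblyContext(mesh)
    rng = np.random.default_rng(1)
    n = mesh.n_nodes
    u = rng.normal(size=(n, dim))
    p = rng.normal(size=n)
    a = rng.normal(size=(n, dim))
    st = StabilizationSettings("present", 3.0, 1e-2)
    om = 5.0
    c_u, c_a = 0.7, 0.3
    R0 = assemble_residual(ctx, PROPS, u, p, a, 0.0, None, st, om,
                           apply_bc=False)
    K = assemble_tangent(ctx, PROPS, u, p, a, 0.0, None, st, om,
                         c_u=c_u, c_a=c_a, apply_bc=False)
    dv = rng.normal(size=(n, dim + 1))
    eps = 1e-7
    R1 = assemble_residual(ctx, PROPS, u + eps * c_u * dv[:, :dim],
                           p + eps * dv[:, dim],
                           a + eps * c_a * dv[:, :dim], 0.0, None, st, om,
                           apply_bc=False)
    fd = (R1 - R0) / eps
    err = np.linalg.norm(K @ dv.ravel() - fd) / np.linalg.norm(fd)
    assert err < 1e-5


def test_tangent_sparsity_is_node_adjacency():
    mesh = generate_channel_mesh_2d(2, 1, 3, 2)
    ctx = AssemblyContext(mesh)
    u = np.ones((mesh.n_nodes, 2))
    K = assemble_tangent(ctx, PROPS, u, np.ones(mesh.n_nodes),
                         np.zeros_like(u), 0.0, None,
                         StabilizationSettings(dt=0.1), 2.0, apply_bc=False)
    K = K.tocoo()
    adj = set()
    for el in mesh.elements:
        for i in el:
            for j in el:
                adj.add((int(i), int(j)))
    for r, c in zip(K.row, K.col):
        assert (r // 3, c // 3) in adj


def test_constant_stress_equilibrium():
    """A linear shear field with matching boundary tractions is a discrete
    equilibrium: the full stabilized residual vanishes identically."""
    mesh = generate_channel_mesh_2d(1.0, 1.0, 1, 1)  # 2 elements
    ctx = AssemblyContext(mesh)
    u = np.stack([mesh.nodes[:, 1], np.zeros(mesh.n_nodes)], axis=1)
    p = np.zeros(mesh.n_nodes)
    a = np.zeros_like(u)
    sigma = PROPS.mu * np.array([[0.0, 1.0], [1.0, 0.0]])

    def traction(patch):
        _, normals = mesh.facet_areas_normals(patch)
        n = normals[0]
        return lambda x, t, n=n: np.tile(sigma @ n, (x.shape[0], 1))

    bcs = BCSet(neumann=[NeumannBC(nm, traction(nm))
                         for nm in mesh.boundary_patches])
    R = assemble_residual(ctx, PROPS, u, p, a, 0.0, bcs,
                          StabilizationSettings(dt=0.1), 3.0, apply_bc=False)
    assert np.abs(R).max() < 1e-12


def test_galerkin_linearity_in_data():
    """With stabilization off, the Galerkin residual is linear in the data
    (rho, mu, p, f) at frozen velocity."""
    mesh = generate_channel_mesh_2d(1, 1, 2, 2, perturb=0.1)
    ctx = AssemblyContext(mesh)
    rng = np.random.default_rng(6)
    u = rng.normal(size=(mesh.n_nodes, 2))
    p = rng.normal(size=mesh.n_nodes)
    a = rng.normal(size=(mesh.n_nodes, 2))
    f = rng.normal(size=2)
    R1 = assemble_residual(ctx, FluidProperties(1.0, 0.05), u, p, a, 0.0,
                           BCSet(body_force=f), None, apply_bc=False)
    R2 = assemble_residual(ctx, FluidProperties(2.0, 0.10), u, 2 * p, a, 0.0,
                           BCSet(body_force=f), None, apply_bc=False)
    vel = np.ones(ctx.ndof, dtype=bool).reshape(-1, 3)
    vel[:, 2] = False  # continuity rows carry no data, they stay unchanged
    vel = vel.ravel()
    assert np.allclose(R2[vel], 2 * R1[vel], rtol=1e-12, atol=1e-13)
    assert np.allclose(R2[~vel], R1[~vel], rtol=1e-12, atol=1e-13)


class TestParabolicInlet:
    def test_pipe_amplitude(self):
        mesh = generate_pipe_mesh_3d(1.0, 3.0, 0.34, axial_h=1.5)
        prof = parabolic_inlet_profile(mesh, "inlet", 10.0, pipe_radius=1.0)
        g = prof(np.array([[0.0, 0.0, 0.0]]), 0.0)
        assert g[0, 2] == pytest.approx(20.0 / np.pi)  # 6.366 cm/s
        assert g[0, 0] == g[0, 1] == 0.0

    def test_discrete_flux_on_fine_inlet(self):
        mesh = generate_pipe_mesh_3d(1.0, 1.0, 0.085, axial_h=0.5)
        prof = parabolic_inlet_profile(mesh, "inlet", 10.0, pipe_radius=1.0)
        patch = mesh.patch("inlet")
        g = np.zeros((mesh.n_nodes, 3))
        nodes = np.unique(patch.facets)
        g[nodes] = prof(mesh.nodes[nodes], 0.0)
        area, normal = mesh.facet_areas_normals(patch)
        flux = 0.0
        for f, ar, n in zip(patch.facets, area, normal):
            flux += ar * (g[f, 2].mean() * -n[2])
        assert flux == pytest.approx(10.0, rel=5e-3)

    def test_zero_rate(self):
        mesh = generate_channel_mesh_2d(3, 1, 3, 3)
        prof = parabolic_inlet_profile(mesh, "inlet", 0.0, channel_height=1.0)
        assert np.all(prof(mesh.nodes[:4], 0.0) == 0.0)

    def test_channel_mean(self):
        prof = parabolic_inlet_profile(generate_channel_mesh_2d(3, 1, 2, 2),
                                       "inlet", 1.0, channel_height=1.0)
        g = prof(np.array([[0.0, 0.5]]), 0.0)
        assert g[0, 0] == pytest.approx(1.5)  # centerline of mean-1 profile


class TestMMSForcing:
    x, y, t = sm.symbols("x y t")

    def test_hand_derived_channel_forcing(self):
        props = FluidProperties(1.0, 0.05)
        f, u_fn, _ = mms_forcing((sm.sin(self.t) * self.y * (1 - self.y),
                                  sm.Integer(0)), sm.Integer(0), props,
                                 coords=(self.x, self.y))
        pts = np.array([[0.2, 0.3], [0.8, 0.9]])
        tt = 0.7
        yv = pts[:, 1]
        expect_x = (np.cos(tt) * yv * (1 - yv)
                    + 2 * props.mu * np.sin(tt)) / props.rho
        got = f(pts, tt)
        assert np.allclose(got[:, 0], expect_x)
        assert np.allclose(got[:, 1], 0.0)

    def test_rigid_rotation_centripetal_balance(self):
        props = FluidProperties(2.0, 0.01)
        f, _, _ = mms_forcing((-self.y, self.x),
                              props.rho * (self.x**2 + self.y**2) / 2,
                              props, coords=(self.x, self.y))
        pts = np.random.default_rng(0).normal(size=(5, 2))
        assert np.allclose(f(pts, 0.0), 0.0, atol=1e-12)

    def test_non_solenoidal_rejected(self):
        with pytest.raises(ValueError):
            mms_forcing((self.x, self.y), sm.Integer(0),
                        FluidProperties(1, 1), coords=(self.x, self.y))


def test_equal_order_checkerboarding_without_stabilization():
    """With tau = nu_C = 0 the equal-order pair loses pressure control: the
    node-to-node pressure oscillation grows far beyond the stabilized run."""
    import scipy.sparse.linalg as spla

    mesh = generate_channel_mesh_2d(3, 1, 10, 4)
    ctx = AssemblyContext(mesh)
    props = FluidProperties(1.0, 0.01)
    inflow = parabolic_inlet_profile(mesh, "inlet", 1.0, channel_height=1.0)
    bcs = BCSet(dirichlet=[DirichletBC("inlet", (0, 1), inflow),
                           DirichletBC("wall_bottom", (0, 1), 0.0),
                           DirichletBC("wall_top", (0, 1), 0.0)])
    u0 = np.zeros((mesh.n_nodes, 2))
    p0 = np.zeros(mesh.n_nodes)
    a0 = np.zeros_like(u0)
    cdofs, cvals = bcs.constrained(mesh, 0.0)
    node, comp = cdofs // 3, cdofs % 3
    u0[node, comp] = cvals

    def singvals(settings):
        K = assemble_tangent(ctx, props, u0, p0, a0, 0.0, bcs, settings,
                             0.0, c_u=1.0, c_a=0.0).toarray()
        return np.linalg.svd(K, compute_uv=False), K

    s_stab, _ = singvals(StabilizationSettings("present", dt=1e-2))
    s_none, K_none = singvals(None)
    # stabilized system is uniformly invertible; unstabilized one carries
    # exact zero modes (spurious pressure / checkerboard modes)
    assert s_stab[-1] / s_stab[0] > 1e-4
    assert s_none[-1] / s_none[0] < 1e-12
    # the null mode is a pressure mode
    _, _, vt = np.linalg.svd(K_none)
    null = vt[-1].reshape(-1, 3)
    p_frac = np.sum(null[:, 2]**2) / np.sum(null**2)
    assert p_frac > 0.9
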