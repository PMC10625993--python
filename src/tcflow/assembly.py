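"""Stabilized weak-form assembly on P1/P1 simplices.

The discrete problem is the Galerkin form of the incompressible
Navier-Stokes equations supplemented with three elemental stabilization
terms: SUPG and PSPG (both weighted by tau_SUPG, acting on the strong
momentum residual R_M) and a grad-div term (weighted by rho*nu_C, acting on
the strong continuity residual R_C = div u).  Velocity and pressure share
the same linear interpolation; the PSPG term is what makes that equal-order
pairing stable.

For linear simplices the viscous second derivative in R_M vanishes
identically, so the strong momentum residual reduces to
``R_M = rho (a + u.grad u - f) + grad p``.

Unknown ordering is node-major interleaved: dof(n, c) = n*(dim+1) + c with
c < dim the velocity components and c = dim the pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh, compute_metric_tensors, shape_gradients
from .stabilization import (StabilizationSettings, _tri_quadrature,
                            tau_supg_conventional, tau_supg_present)

__all__ = [
    "FluidProperties",
    "State",
    "DirichletBC",
    "NeumannBC",
    "BCSet",
    "ShapeFunctionTable",
    "AssemblyContext",
    "strong_residuals",
    "assemble_residual",
    "assemble_tangent",
    "apply_dirichlet_matrix",
    "parabolic_inlet_profile",
    "mms_forcing",
]


@dataclass
class FluidProperties:
    """Newtonian fluid constants (units follow the case: CGS or SI)."""

    rho: float
    mu: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity mu/rho."""
        return self.mu / self.rho


@dataclass
class State:
    """Nodal solution at one time level: velocity, pressure, acceleration."""

    u: np.ndarray  # (n_nodes, dim)
    p: np.ndarray  # (n_nodes,)
    a: np.ndarray  # (n_nodes, dim)
    t: float = 0.0

    @classmethod
    def zero(cls, mesh: Mesh, t: float = 0.0) -> "State":
        return cls(np.zeros((mesh.n_nodes, mesh.dim)), np.zeros(mesh.n_nodes),
                   np.zeros((mesh.n_nodes, mesh.dim)), t)

    def copy(self) -> "State":
        return State(self.u.copy(), self.p.copy(), self.a.copy(), self.t)


@dataclass
class DirichletBC:
    """Prescribed velocity components on a patch.

    value: scalar, (len(comps),) vector, or callable(coords, t) returning
    (n_nodes_on_patch, len(comps)).
    """

    patch: str
    comps: tuple[int, ...]
    value: object = 0.0


@dataclass
class NeumannBC:
    """Prescribed traction h on a patch (zero traction needs no entry)."""

    patch: str
    traction: object  # (dim,) array or callable(coords, t) -> (n, dim)


@dataclass
class BCSet:
    dirichlet: list[DirichletBC] = field(default_factory=list)
    neumann: list[NeumannBC] = field(default_factory=list)
    body_force: object = None  # None | (dim,) | callable(x, t) -> (..., dim)
    pin_pressure_node: int | None = None  # gauge fix for all-Dirichlet cases

    def constrained(self, mesh: Mesh, t: float):
        """(velocity dof indices, prescribed values), conflict-checked."""
        nd = mesh.dim + 1
        vals: dict[int, float] = {}
        for bc in self.dirichlet:
            patch = mesh.patch(bc.patch)
            nodes = np.unique(patch.facets)
            coords = mesh.nodes[nodes]
            if callable(bc.value):
                v = np.asarray(bc.value(coords, t), dtype=np.float64)
                v = v.reshape(nodes.size, len(bc.comps))
            else:
                v = np.broadcast_to(
                    np.atleast_1d(np.asarray(bc.value, dtype=np.float64)),
                    (nodes.size, len(bc.comps))).copy()
            for jc, c in enumerate(bc.comps):
                for n, val in zip(nodes, v[:, jc]):
                    dof = int(n) * nd + c
                    if dof in vals and abs(vals[dof] - val) > 1e-10 * (
                            1.0 + abs(val)):
                        raise ValueError(
                            f"conflicting Dirichlet values at node {n}, "
                            f"component {c}")
                    vals[dof] = float(val)
        dofs = np.fromiter(vals.keys(), dtype=np.int64)
        order = np.argsort(dofs)
        values = np.fromiter(vals.values(), dtype=np.float64)[order]
        return dofs[order], values


class ShapeFunctionTable:
    """P1 basis values/gradients at the degree-2 quadrature points.

    Basis values coincide with the barycentric coordinates of the points;
    parent gradients are constant.  Invariants: partition of unity and
    zero-sum gradients.
    """

    def __init__(self, dim: int):
        self.dim = dim
        w, bary = _tri_quadrature(dim)
        self.weights = w  # (n_gp,), sums to 1 (reference measure normalized)
        self.N = bary  # (n_gp, dim+1)
        grads = np.zeros((dim + 1, dim))
        grads[1:, :] = np.eye(dim)
        grads[0, :] = -1.0
        self.parent_gradients = grads

    @property
    def n_gp(self) -> int:
        return self.N.shape[0]


class AssemblyContext:
    """Precomputed per-mesh geometry shared by residual/tangent assembly."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.dim = mesh.dim
        self.table = ShapeFunctionTable(mesh.dim)
        self.vol, self.grads = shape_gradients(mesh)
        if np.any(self.vol <= 0):
            raise ValueError("mesh has non-positive element volumes")
        self.G = compute_metric_tensors(mesh)
        self.trG = np.trace(self.G, axis1=1, axis2=2)
        # Gauss point physical coordinates (n_el, n_gp, dim)
        xe = mesh.nodes[mesh.elements]
        self.gp_coords = np.einsum("ga,ead->egd", self.table.N, xe, optimize=True)
        nd = mesh.dim + 1
        self.ndof = mesh.n_nodes * nd
        # global dof indices per element, node-major (n_el, (dim+1)*(dim+1))
        el = mesh.elements
        self.eldofs = (el[:, :, None] * nd + np.arange(nd)[None, None, :]
                       ).reshape(mesh.n_el, -1)


def strong_residuals(u_gp, grad_u, grad_p, a_gp, props: FluidProperties,
                     f_gp=None):
    """Pointwise strong residuals for P1 interpolants.

    R_M = rho (a + u.grad u - f) + grad p  (the viscous Laplacian of a P1
    field is identically zero elementwise), R_C = div u.  Broadcasts over
    leading axes.
    """
    u_gp = np.asarray(u_gp, dtype=np.float64)
    grad_u = np.asarray(grad_u, dtype=np.float64)
    conv = np.einsum("...j,...ij->...i", u_gp, grad_u, optimize=True)
    acc = np.asarray(a_gp, dtype=np.float64) + conv
    if f_gp is not None:
        acc = acc - np.asarray(f_gp, dtype=np.float64)
    r_m = props.rho * acc + np.asarray(grad_p, dtype=np.float64)
    r_c = np.einsum("...ii->...", grad_u)
    return r_m, r_c


def _body_force_at(ctx: AssemblyContext, bcs: BCSet, t: float):
    if bcs is None or bcs.body_force is None:
        return None
    f = bcs.body_force
    if callable(f):
        return np.asarray(f(ctx.gp_coords, t), dtype=np.float64)
    return np.broadcast_to(np.asarray(f, dtype=np.float64),
                           ctx.gp_coords.shape)


def _gauss_tau(ctx, props, u_gp, settings: StabilizationSettings, omega):
    Gq = ctx.G[:, None, :, :]
    if settings.formulation == "conventional":
        return tau_supg_conventional(settings.dt, u_gp, Gq, props.nu,
                                     settings.C_I)
    return tau_supg_present(omega, u_gp, Gq, props.nu, settings.C_I)


def assemble_residual(ctx: AssemblyContext, props: FluidProperties,
                      u: np.ndarray, p: np.ndarray, a: np.ndarray, t: float,
                      bcs: BCSet | None,
                      settings: StabilizationSettings | None,
                      omega: float = 0.0,
                      frozen_tau: np.ndarray | None = None,
                      apply_bc: bool = True,
                      return_tau: bool = False):
    """Assemble the global residual of the stabilized weak form.

    ``u, a`` are the intermediate-time nodal fields, ``p`` the pressure.
    ``settings=None`` disables all stabilization (pure Galerkin), which is
    useful to demonstrate equal-order pressure checkerboarding.
    ``frozen_tau`` ((n_el, n_gp)) bypasses the tau evaluation — used by the
    tangent consistency check, where tau is frozen w.r.t. the increment.
    Dirichlet rows are zeroed when ``apply_bc``.
    """
    mesh, tab = ctx.mesh, ctx.table
    d, nn = ctx.dim, ctx.dim + 1
    el = mesh.elements
    W, N = tab.weights, tab.N

    ue, pe, ae = u[el], p[el], a[el]
    grad_u = np.einsum("eai,eaj->eij", ue, ctx.grads, optimize=True)
    grad_p = np.einsum("ea,eaj->ej", pe, ctx.grads, optimize=True)
    u_gp = np.einsum("ga,eai->egi", N, ue, optimize=True)
    a_gp = np.einsum("ga,eai->egi", N, ae, optimize=True)
    f_gp = _body_force_at(ctx, bcs, t)

    conv = np.einsum("egj,eij->egi", u_gp, grad_u, optimize=True)
    gal = a_gp + conv
    if f_gp is not None:
        gal = gal - f_gp
    rm = props.rho * gal + grad_p[:, None, :]
    divu = np.einsum("eii->e", grad_u)
    pbar = pe.mean(axis=1)

    Rv = np.zeros((mesh.n_el, nn, d))
    Rp = np.zeros((mesh.n_el, nn))

    # Galerkin momentum (mass + convection - forcing)
    Rv += props.rho * np.einsum("g,ga,egi->eai", W, N, gal, optimize=True)
    # stress: -p div w + 2 mu eps(w):eps(u)   (integrand constant except p)
    sym = grad_u + np.swapaxes(grad_u, 1, 2)
    Rv += np.einsum("eaj,eij->eai", ctx.grads, props.mu * sym, optimize=True)
    Rv -= pbar[:, None, None] * ctx.grads
    # Galerkin continuity
    Rp += divu[:, None] / nn

    if settings is not None:
        if frozen_tau is not None:
            tau = frozen_tau
        else:
            tau = _gauss_tau(ctx, props, u_gp, settings, omega)
        nuc = 1.0 / (ctx.trG[:, None] * tau)
        adv_w = np.einsum("egi,eai->ega", u_gp, ctx.grads, optimize=True)  # u . grad N_a
        Rv += np.einsum("g,eg,ega,egi->eai", W, tau, adv_w, rm, optimize=True)
        nuc_bar = np.einsum("g,eg->e", W, nuc, optimize=True)
        Rv += props.rho * (nuc_bar * divu)[:, None, None] * ctx.grads
        Rp += np.einsum("g,eg,eai,egi->ea", W, tau, ctx.grads, rm, optimize=True) / props.rho
    # scale by element measure and scatter
    Rv *= ctx.vol[:, None, None]
    Rp *= ctx.vol[:, None]

    R = np.zeros(ctx.ndof)
    loc = np.concatenate([Rv, Rp[:, :, None]], axis=2).reshape(mesh.n_el, -1)
    np.add.at(R, ctx.eldofs.ravel(), loc.ravel())

    # Neumann boundary term  - int_Gamma w . h
    if bcs is not None:
        for nb in bcs.neumann:
            _add_neumann(ctx, nb, t, R)

    if apply_bc and bcs is not None:
        dofs, _ = bcs.constrained(mesh, t)
        R[dofs] = 0.0
        if bcs.pin_pressure_node is not None:
            R[bcs.pin_pressure_node * nn + d] = 0.0
    if return_tau:
        return R, (tau if settings is not None else None)
    return R


def _add_neumann(ctx: AssemblyContext, nb: NeumannBC, t: float, R: np.ndarray):
    mesh = ctx.mesh
    d, nd = ctx.dim, ctx.dim + 1
    patch = mesh.patch(nb.patch)
    if patch.facets.size == 0:
        return
    area, _ = mesh.facet_areas_normals(patch)
    coords = mesh.nodes[patch.facets]  # (nf, d, dim)
    if callable(nb.traction):
        h = np.asarray(nb.traction(coords.reshape(-1, d), t),
                       dtype=np.float64).reshape(coords.shape)
    else:
        h = np.broadcast_to(np.asarray(nb.traction, dtype=np.float64),
                            coords.shape)
    # facet P1 mass matrix: measure/((k)(k+1)) * (1 + delta), k = dim
    M = (np.ones((d, d)) + np.eye(d)) / (d * (d + 1))
    contrib = np.einsum("f,ab,fbi->fai", area, M, h, optimize=True)
    dofs = patch.facets[:, :, None] * nd + np.arange(d)[None, None, :]
    np.subtract.at(R, dofs.ravel(), contrib.ravel())


def assemble_tangent(ctx: AssemblyContext, props: FluidProperties,
                     u: np.ndarray, p: np.ndarray, a: np.ndarray, t: float,
                     bcs: BCSet | None,
                     settings: StabilizationSettings | None,
                     omega: float = 0.0,
                     c_u: float = 1.0, c_a: float = 0.0,
                     apply_bc: bool = True,
                     linearize_tau: bool = True) -> sp.csr_matrix:
    """Consistent tangent d R / d increment (omega frozen).

    ``c_u`` and ``c_a`` are the chain-rule factors of the time integrator:
    the velocity and acceleration responses to the solver increment
    (for generalized-alpha Newton on the acceleration increment,
    c_u = alpha_f * gamma * dt and c_a = alpha_m; for a steady solve on the
    velocity, c_u = 1, c_a = 0).  Pressure columns always respond directly.

    ``linearize_tau`` includes d tau/d u and d nu_C/d u; without it
    (quasi-Newton) the iteration can stagnate above the required residual
    drop in strongly evolving flows, because the stabilization parameters
    are most velocity-sensitive exactly where the flow locally stagnates.
    The global frequency omega is always treated as frozen within the step.
    """
    mesh, tab = ctx.mesh, ctx.table
    d, nn = ctx.dim, ctx.dim + 1
    el = mesh.elements
    W, N = tab.weights, tab.N
    ue, pe, ae = u[el], p[el], a[el]
    grad_u = np.einsum("eai,eaj->eij", ue, ctx.grads, optimize=True)
    grad_p = np.einsum("ea,eaj->ej", pe, ctx.grads, optimize=True)
    u_gp = np.einsum("ga,eai->egi", N, ue, optimize=True)
    a_gp = np.einsum("ga,eai->egi", N, ae, optimize=True)
    f_gp = _body_force_at(ctx, bcs, t)
    conv = np.einsum("egj,eij->egi", u_gp, grad_u, optimize=True)
    gal = a_gp + conv
    if f_gp is not None:
        gal = gal - f_gp
    rm = props.rho * gal + grad_p[:, None, :]
    divu = np.einsum("eii->e", grad_u)

    g = ctx.grads  # (e, a, i)
    adv = np.einsum("egi,eai->ega", u_gp, g, optimize=True)  # u . grad N_a
    eye = np.eye(d)
    rho, mu = props.rho, props.mu

    # K blocks: vv (e,a,i,b,k), vp (e,a,i,b), pv (e,a,b,k), pp (e,a,b)
    Mab = np.einsum("g,ga,gb->ab", W, N, N, optimize=True)  # consistent P1 mass (parent)
    vv = np.zeros((mesh.n_el, nn, d, nn, d))
    vv += c_a * rho * np.einsum("ab,ik->aibk", Mab, eye, optimize=True)[None]
    vv += c_u * rho * (
        np.einsum("g,ga,egb,ik->eaibk", W, N, adv, eye, optimize=True)
        + np.einsum("ab,eik->eaibk", Mab, grad_u, optimize=True))
    vv += c_u * mu * (
        np.einsum("eaj,ebj,ik->eaibk", g, g, eye, optimize=True)
        + np.einsum("ebi,eak->eaibk", g, g, optimize=True))
    vp = -np.einsum("eai->eai", g)[:, :, :, None] * (1.0 / nn)
    vp = np.repeat(vp, nn, axis=3)
    pv = c_u * np.einsum("ebk->ebk", g)[:, None, :, :] / nn
    pv = np.repeat(pv, nn, axis=1)
    pp = np.zeros((mesh.n_el, nn, nn))

    if settings is not None:
        tau = _gauss_tau(ctx, props, u_gp, settings, omega)
        nuc = 1.0 / (ctx.trG[:, None] * tau)
        # SUPG: rows (a,i) += sum_g W tau [ adv_a drm_i + c_u N_b g_ak rm_i ]
        drm_scal = c_a * np.einsum("g,eg,ega,gb->eab", W, tau, adv, N, optimize=True) \
            + c_u * np.einsum("g,eg,ega,egb->eab", W, tau, adv, adv, optimize=True)
        vv += rho * np.einsum("eab,ik->eaibk", drm_scal, eye, optimize=True)
        vv += c_u * rho * np.einsum("g,eg,ega,gb,eik->eaibk", W, tau, adv, N,
                                    grad_u, optimize=True)
        vv += c_u * np.einsum("g,eg,gb,eak,egi->eaibk", W, tau, N, g, rm, optimize=True)
        vp += np.einsum("g,eg,ega,ebi->eaib", W, tau, adv, g, optimize=True)
        # grad-div
        nuc_bar = np.einsum("g,eg->e", W, nuc, optimize=True)
        vv += c_u * rho * np.einsum("e,eai,ebk->eaibk", nuc_bar, g, g, optimize=True)
        # PSPG rows a
        pv += c_a * np.einsum("g,eg,gb,eak->eabk", W, tau, N, g, optimize=True) \
            + c_u * np.einsum("g,eg,egb,eak->eabk", W, tau, adv, g, optimize=True) \
            + c_u * np.einsum("g,eg,gb,eai,eik->eabk", W, tau, N, g, grad_u, optimize=True)
        pp += np.einsum("g,eg,eai,ebi->eab", W, tau, g, g, optimize=True) / rho
        if linearize_tau:
            # d tau/d u_gp = -tau^3 (G u_gp); d nu_C/d u_gp = tau (G u)/tr(G)
            Gu = np.einsum("ekj,egj->egk", ctx.G, u_gp, optimize=True)
            dtau = -np.einsum("eg,egk->egk", tau**3, Gu, optimize=True)
            vv += c_u * np.einsum("g,ega,egi,egk,gb->eaibk", W, adv, rm,
                                  dtau, N, optimize=True)
            pv += (c_u / rho) * np.einsum("g,eai,egi,egk,gb->eabk", W, g, rm,
                                          dtau, N, optimize=True)
            dnuc = np.einsum("eg,egk->egk", tau, Gu, optimize=True) / ctx.trG[:, None, None]
            vv += c_u * rho * np.einsum("g,eai,e,egk,gb->eaibk", W, g, divu,
                                        dnuc, N, optimize=True)

    # pack into (e, nl, nl), node-major interleaved local dofs
    nl = nn * (d + 1)
    K = np.zeros((mesh.n_el, nn, d + 1, nn, d + 1))
    K[:, :, :d, :, :d] = vv
    K[:, :, :d, :, d] = vp
    K[:, :, d, :, :d] = pv
    K[:, :, d, :, d] = pp
    K *= ctx.vol[:, None, None, None, None]
    K = K.reshape(mesh.n_el, nl, nl)

    rows = np.repeat(ctx.eldofs, nl, axis=1).ravel()
    cols = np.tile(ctx.eldofs, (1, nl)).ravel()
    A = sp.coo_matrix((K.ravel(), (rows, cols)),
                      shape=(ctx.ndof, ctx.ndof)).tocsr()

    if apply_bc and bcs is not None:
        cdofs, _ = bcs.constrained(mesh, t)
        cdofs = list(cdofs)
        if bcs.pin_pressure_node is not None:
            cdofs.append(bcs.pin_pressure_node * (d + 1) + d)
        A = apply_dirichlet_matrix(A, np.asarray(cdofs, dtype=np.int64))
    return A


def apply_dirichlet_matrix(A: sp.csr_matrix, dofs: np.ndarray) -> sp.csr_matrix:
    """Row replacement with matching column elimination: constrained rows
    and columns are zeroed and the diagonal set to one (increments at
    constrained dofs are zero, so the elimination is exact)."""
    if dofs.size == 0:
        return A
    mask = np.zeros(A.shape[0], dtype=bool)
    mask[dofs] = True
    A = A.tocoo()
    keep = ~(mask[A.row] | mask[A.col])
    data = np.concatenate([A.data[keep], np.ones(dofs.size)])
    rows = np.concatenate([A.row[keep], dofs])
    cols = np.concatenate([A.col[keep], dofs])
    return sp.coo_matrix((data, (rows, cols)), shape=A.shape).tocsr()


# ---------------------------------------------------------------------------
# boundary data helpers


def parabolic_inlet_profile(mesh: Mesh, patch: str, flow_rate: float, *,
                            pipe_radius: float | None = None,
                            channel_height: float | None = None,
                            axis_center=(0.0, 0.0)):
    """Dirichlet velocity profile carrying a prescribed flow rate.

    3D pipe (give ``pipe_radius``): axial profile
    u_z = u_max (1 - r^2/R^2) with u_max = 2 Q / (pi R^2).

    2D channel (give ``channel_height``): per-unit-depth rate Q',
    u_x = 1.5 (Q'/H) (1 - (2y/H - 1)^2).

    Returns a callable g(coords, t) -> (n, dim) suitable for DirichletBC.
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    if (pipe_radius is None) == (channel_height is None):
        raise ValueError("give exactly one of pipe_radius / channel_height")
    if pipe_radius is not None:
        R = pipe_radius
        u_max = 2.0 * flow_rate / (np.pi * R**2)
        cx, cy = axis_center

        def profile(coords, t):
            r2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
            if np.any(r2 > R**2 * (1 + 1e-9)):
                raise ValueError("inlet node outside the patch radius")
            g = np.zeros((coords.shape[0], 3))
            g[:, 2] = u_max * (1.0 - r2 / R**2)
            return g
    else:
        H = channel_height
        u_max = 1.5 * flow_rate / H

        def profile(coords, t):
            y = coords[:, 1]
            g = np.zeros((coords.shape[0], 2))
            g[:, 0] = u_max * (1.0 - (2.0 * y / H - 1.0) ** 2)
            return g

    return profile


def mms_forcing(u_exprs, p_expr, props: FluidProperties, coords=None):
    """Manufactured-solution forcing: given analytic (u, p), return the body
    force f with which they exactly solve the momentum equation, plus
    lambdified evaluators for u and p.

    ``u_exprs`` are sympy expressions in (x, y[, z], t); the velocity must be
    solenoidal (checked symbolically).  Returns (f, u_fn, p_fn), each a
    callable(points, t) with points of shape (..., dim).
    """
    import sympy as sm

    dim = len(u_exprs)
    if coords is None:
        coords = sm.symbols("x y z")[:dim]
    tsym = sm.Symbol("t")
    div = sum(sm.diff(u_exprs[i], coords[i]) for i in range(dim))
    if sm.simplify(div) != 0:
        raise ValueError("manufactured velocity is not divergence-free")

    f_exprs = []
    for i in range(dim):
        conv = sum(u_exprs[j] * sm.diff(u_exprs[i], coords[j])
                   for j in range(dim))
        lap = sum(sm.diff(u_exprs[i], c, 2) for c in coords)
        fi = (props.rho * (sm.diff(u_exprs[i], tsym) + conv)
              + sm.diff(p_expr, coords[i]) - props.mu * lap) / props.rho
        # f enters R_M as rho*f, so divide rho back out
        f_exprs.append(sm.simplify(fi))

    def lamb(exprs):
        fns = [sm.lambdify((*coords, tsym), e, "numpy") for e in exprs]

        def evaluate(points, t):
            pts = np.asarray(points, dtype=np.float64)
            args = [pts[..., i] for i in range(dim)]
            out = np.stack(
                [np.broadcast_to(fn(*args, t), pts[..., 0].shape)
                 for fn in fns], axis=-1)
            return np.ascontiguousarray(out, dtype=np.float64)

        return evaluate

    f_fn = lamb(f_exprs)
    u_fn = lamb(u_exprs)
    p_single = sm.lambdify((*coords, tsym), p_expr, "numpy")

    def p_fn(points, t):
        pts = np.asarray(points, dtype=np.float64)
        args = [pts[..., i] for i in range(dim)]
        return np.broadcast_to(p_single(*args, t), pts[..., 0].shape).astype(
            np.float64)

    return f_fn, u_fn, p_fn
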