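# Methods

## Model and discretization

`tcflow` solves the incompressible Navier–Stokes equations

    rho (du/dt + u . grad u - f) - div sigma = 0,   div u = 0,
    sigma = -p I + 2 mu eps(u),

on simplex meshes with equal-order linear (P1/P1) interpolation for
velocity and pressure.  The Galerkin form is stabilized by three elemental
terms: SUPG and PSPG, both weighted by the stabilization time scale
tau_SUPG acting on the strong momentum residual
`R_M = rho (a + u.grad u - f) + grad p` (the viscous second derivative of a
P1 field vanishes elementwise, so it is dropped — the method is therefore
formally first-order consistent in the stabilization terms), and a
grad-div term weighted by `rho nu_C` acting on `R_C = div u`.  The viscous
Galerkin term uses the symmetric-gradient form `2 mu eps(w):eps(u)`, not
the Laplacian form, and the Neumann ("zero traction") outlet is the natural
condition of that form.

Two definitions of the stabilization time scale are implemented:

    conventional: tau = ((2/dt)^2 + u.Gu + C_I nu^2 G:G)^(-1/2)
    present:      tau = (omega^2  + u.Gu + C_I nu^2 G:G)^(-1/2)

with `nu_C = 1/(tr(G) tau)` in both cases (the active formulation's tau is
used, for self-consistency) and C_I = 3 for linear elements.  G is the
element covariant metric built from the inverse affine Jacobian of the map
from the unit right simplex with local node 0 at the parent origin.  This
parent convention matters: C_I = 3 is calibrated for it, and changing the
convention rescales tau.  G depends mildly on which local node sits at the
parent origin; the mesh generators fix a reproducible local ordering.

The global flow frequency

    omega = ||du/dt||_L2(Omega) / ||u||_L2(Omega)

is evaluated once per time step from the previous step's discrete velocity
and acceleration (both are state variables of the generalized-alpha
integrator) and held frozen within the Newton loop.  It falls back to
2/dt on the first step and whenever ||u||_L2 < epsilon_u (default 1e-14 in
case units): the divide-by-zero concern that motivates the first-step rule
persists for any later quiescent state.  An ALE variant for moving meshes,
`omega_ale`, uses the acceleration at mesh nodes over ||u - u_mesh|| and is
Galilean invariant; it is provided as a standalone utility on prescribed
mesh-velocity fields (no ALE solver is included).

L2 norms use the degree-2 Gauss rules (3-point triangle, 4-point
tetrahedron), which integrate squares of P1 fields exactly; all Galerkin
mass and advection integrals use the same rules.

## Time integration and solvers

Time stepping is the implicit generalized-alpha method for first-order
systems, parameterized by the spectral radius rho_inf (default 0.5;
sensitivity on the shedding benchmark is weak — changing rho_inf from 0.5
to 0 moves the bulk statistics by under 3%).  The predictor is
same-velocity / scaled-acceleration (`a0 = ((gamma-1)/gamma) a_n`).
Dirichlet values are imposed strongly with the acceleration made consistent
with the update relation; constrained tangent rows and columns are
eliminated exactly (no penalty).

Each step performs Newton–Raphson iterations on the true assembled
intermediate-time residual until it drops by `newton_drop_orders`
(default 3; the pipe preset uses 3.5) with an absolute floor of 1e-12,
globalized by a backtracking line search.  The tangent linearizes
everything except omega — including d tau/d u and d nu_C/d u.  A
frozen-tau quasi-Newton variant (`linearize_tau=False`) is retained but not
used by default: in strongly evolving bluff-body flow it stagnates above
the required drop, because tau is most velocity-sensitive exactly where the
flow locally stagnates.  A modified-Newton mode (`tangent_refresh="step"`)
reuses the first factorization of a step and refreshes it when the residual
contraction degrades beyond 0.2 per iteration.

Linear systems are solved with restarted GMRES (restart 200, relative
tolerance 1e-2, cap 2000 inner iterations) preconditioned by an exact or
incomplete LU factorization that may be reused for several steps
(`precond_refresh_steps`); the operator is always the current tangent, so a
stale preconditioner costs Krylov iterations, never accuracy.  A direct
sparse solve backs up the rare GMRES stall.  Steady states are computed by
damped Newton on the steady residual (a = 0), which is exactly the
generalized-alpha fixed point of the transient — verified by a test that
advances one transient step from the steady solution and finds it
unchanged.  Everything is deterministic: reruns and checkpoint restarts are
bitwise identical.

## Meshes and what the generators emulate

Three deterministic generators cover the verification geometries: a
structured 2D channel, a graded 2D box with a square hole (conforming
tensor grid, spacing target_h at the obstacle growing geometrically to a
far-field cap, optionally with a resolved wake corridor), and a 3D pipe
(polar fan-plus-rings cross-section extruded to prisms, each split into
three tetrahedra by the smallest-global-index diagonal rule, which is
face-compatible between neighbors).

Generators accept a `perturb` parameter that displaces interior nodes by a
fraction of the local minimum edge length (seeded, boundary preserved).
This matters scientifically: on perfectly structured or extruded meshes the
P1 interpolant of a unidirectional flow is *exactly* divergence-free, so
the conventional formulation's grad-div penalty `nu_C -> infinity` (as
dt -> 0) costs nothing and its hallmark small-dt error never appears.
Generic unstructured meshes do not admit such interpolants; the node
perturbation restores that genericity.  With it, the desk pipe reproduces
the conventional formulation's error growth (dP over-prediction up to ~5x
at dt = 1e-4), whose mechanism is volumetric locking of P1 velocities under
the exploding grad-div penalty, while the present formulation stays within
~2% of Hagen–Poiseuille at every dt.

## Benchmark presets and desk-scale conditions

* `pipe3d` (CGS): R = 1 cm, L = 15 cm, parabolic inlet with Q = 10 mL/s,
  mu = 1 g/(cm s), rho in {1.571, 15.71, 157.1} g/mL for Re in
  {10, 100, 1000}; reference dP = 8 mu L Q/(pi R^4) = 381.97.  Desk mesh:
  in-plane h = 0.25, axial h = 0.2, perturb 0.12 (37.8k tets).  The
  finer axial spacing is deliberate: the present formulation's remaining
  dP error is the first-order SUPG/PSPG consistency error, which scales
  with the advective tau ~ h_axial/u.
* `channel2d` (nondimensional): H = 1, L = 3, mean inlet speed 1,
  nu = 0.01 (Re = 100), plane-Poiseuille reference 12 mu L U/H^2; desk mesh
  36 x 12 cells, perturb 0.2.
* `square2d` (SI): 1 m square in a 29.2 m x 12 m box, centered vertically
  with its center 5 m from the inlet; uniform inlet 51.3 m/s,
  rho = 1.18e-3 kg/m^3, mu = 1.82e-4 kg/(m s) (Re = 332); slip
  (no-penetration) top/bottom walls, zero-traction outlet.  Desk mesh:
  h = D/12 at the square, growth 1.3, far-field cap 2 m (2880 triangles) —
  the same fine-near-square / rapid-coarsening grading philosophy as the
  full 28.5k-element resolution, at a tenth the size.  Desk dt = 4e-3 s
  (~35 steps per shedding period).  Runs start from u = 0 with a geometric
  dt ramp over the first 10 steps and the first-step omega = 2/dt fallback
  extended over the first 0.6 s: an impulsively started bluff-body flow has
  enormous accelerations in regions of near-zero velocity, exactly where an
  omega-based tau is largest.  Statistics use the last 40% of the 5 s run,
  trimmed to an integer number of shedding periods (removing the
  partial-period bias that otherwise dominates dt-to-dt comparisons of the
  rms fluctuations).  `square2d_re22000` reduces mu to 2.75e-6 kg/(m s).
* `mms`: unsteady manufactured solution u = (sin t * y(1-y), 0), p = 0 on
  the unit square with rho = 1, mu = 0.1, dt = 5e-3, T = 0.25, refinement
  ladder n = 8, 16, 32.  The viscosity is chosen so the viscous term of tau
  (the h^2 regime) dominates omega^2 already on the coarsest mesh;
  otherwise the resolution-independent omega floor hides the spatial order.

## Forces and statistics

Wall forces use variationally consistent reactions: the full residual
(Galerkin plus stabilization, no Dirichlet row replacement) is summed over
the patch's velocity dofs and negated; direct integration of the
elementwise P1 traction is the independent cross-check (they agree to ~2%
on resolved fields).  Coefficients are normalized by
q = 1/2 rho U^2 D with U the inlet speed and D the square side.  The
Strouhal number comes from the dominant lift-spectrum frequency (Hann
window, 8x zero padding, parabolic peak interpolation; a mean-crossing
estimator is available as a cross-check).  Fluctuation rms values are
taken about the window mean.

## Known limitations and observed deviations

* **Stability window in dt.**  On desk-scale meshes the present
  formulation's shedding runs are stable for dt >= ~4e-3 s but destabilize
  within ~0.1 s when continued at dt <= 2e-3, even from a developed state:
  the acceleration field grows, omega rises in response (the formulation's
  self-recovery), and the nonlinear solves eventually stall.  This is the
  same failure mode reported for the reference implementation at its
  resolution ("the linear solver may not converge at all"; the FSI case is
  unstable below dt = 5e-4 s); finer meshes widen the window.  The desk
  dt-consistency comparison therefore uses (4e-3, 6e-3) s.
* **Global omega level.**  At desk scale the stationary omega of the
  Re = 332 run is ~6.8 1/s, insensitive to dt (<1% between the two dt) but
  about twice the full-resolution reference value (~3).  omega is a
  domain-integrated fluctuation measure: the near-obstacle region alone
  contributes ~3, and the remainder depends on how far the vortex street
  survives into the coarsening far field — meshes with a resolved wake
  corridor give up to ~12.  A trajectory finite-difference check confirms
  the acceleration norm is genuine flow content, not integrator noise.
  The surface statistics (St = 0.145, Cl' = 0.92) are much closer to the
  reference (0.15, 0.83) than omega is, because they are local quantities.
* **Solver cost ordering.**  With the standard (I)LU-preconditioned GMRES
  used here, the conventional formulation's systems need *more* Krylov
  iterations at small dt than the present one — its tau -> 0 limit removes
  the PSPG pressure block and leaves a near-singular saddle point, while
  its grad-div term stays O(1).  The reference implementation's specialized
  parallel preconditioner (out of scope here) produces the opposite
  ordering.  Iteration counts are logged per step either way.
* No turbulence modeling, non-Newtonian rheology, higher-order elements,
  FSI/ALE solving (only the ALE omega utility), back-flow stabilization, or
  distributed-memory parallelism.
* Synthetic meshes are tensor-product-graded rather than truly
  unstructured; the node perturbation recovers generic-mesh behavior for
  the locking mechanism but not arbitrary connectivity.
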