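"""Stabilization parameters for the SUPG/PSPG + grad-div formulation.

Two definitions of the SUPG/PSPG time scale tau are provided:

* conventional:  tau = ((2/dt)^2 + u.Gu + C_I nu^2 G:G)^(-1/2)
* present:       tau = (omega^2 + u.Gu + C_I nu^2 G:G)^(-1/2)

where G is the element covariant metric tensor and omega is a *global*
physical flow frequency,

    omega = ||du/dt||_L2 / ||u||_L2 ,

evaluated once per time step from the previous step's discrete velocity and
acceleration.  The two definitions coincide when omega = 2/dt; the present
one removes the time-step-size dependence of the stabilized solution because
omega tends to the flow's own frequency content (zero at steady state)
instead of the inverse time step.

The grad-div (continuity least-squares) viscosity is
``nu_C = 1/(tr(G) tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, element_volumes

__all__ = [
    "StabilizationSettings",
    "OmegaState",
    "MeshMotion",
    "tau_supg_conventional",
    "tau_supg_present",
    "nu_c",
    "l2_norm_field",
    "omega_global",
    "omega_ale",
]

DEFAULT_C_I = 3.0  # shape-function-dependent constant for linear simplices


@dataclass
class StabilizationSettings:
    """Configuration of the stabilization formulas.

    formulation: 'conventional' (2/dt transient term) or 'present' (omega).
    C_I: O(1) constant of the viscous term, 3 for linear elements.
    dt: time step size (s), used by the conventional tau and by the
        first-step / zero-velocity fallback omega = 2/dt.
    epsilon_u: guard threshold on ||u||_L2 below which omega falls back to
        2/dt (the divide-by-zero concern of a quiescent field).
    """

    formulation: str = "present"
    C_I: float = DEFAULT_C_I
    dt: float = 1e-3
    epsilon_u: float = 1e-14

    def __post_init__(self) -> None:
        if self.formulation not in ("conventional", "present"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.C_I <= 0 or self.dt <= 0 or self.epsilon_u <= 0:
            raise ValueError("C_I, dt and epsilon_u must be positive")


@dataclass
class OmegaState:
    """Per-run state of the global flow frequency."""

    omega: float = 0.0
    history: list[tuple[float, float]] = field(default_factory=list)
    is_first_step: bool = True

    def update(self, t: float, omega: float) -> None:
        self.omega = float(omega)
        self.history.append((float(t), float(omega)))
        self.is_first_step = False


@dataclass
class MeshMotion:
    """Prescribed mesh motion for the ALE variant of omega."""

    mesh_velocity: np.ndarray  # (n_nodes, dim)
    reference_coords: np.ndarray | None = None


def _quadratic_terms(u_gp, G, nu, C_I):
    u_gp = np.asarray(u_gp, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    adv = np.einsum("...i,...ij,...j->...", u_gp, G, u_gp)
    gg = np.einsum("...ij,...ij->...", G, G)
    return adv + C_I * nu**2 * gg


def tau_supg_conventional(dt, u_gp, G, nu, C_I=DEFAULT_C_I):
    """Conventional SUPG/PSPG time scale with the 2/dt transient term.

    Broadcasts over leading axes of ``u_gp`` (..., d) and ``G`` (..., d, d).
    Satisfies 0 < tau <= dt/2.
    """
    if np.any(np.asarray(dt) <= 0):
        raise ValueError("dt must be positive")
    return ((2.0 / dt) ** 2 + _quadratic_terms(u_gp, G, nu, C_I)) ** -0.5


def tau_supg_present(omega, u_gp, G, nu, C_I=DEFAULT_C_I):
    """Time-consistent SUPG/PSPG time scale with the flow frequency omega.

    Identical to :func:`tau_supg_conventional` when ``omega = 2/dt``.
    Raises on a fully degenerate input (omega = u = nu = 0), which signals a
    quiescent field the caller must guard.
    """
    if np.any(np.asarray(omega) < 0):
        raise ValueError("omega must be non-negative")
    arg = np.asarray(omega, dtype=np.float64) ** 2 + _quadratic_terms(u_gp, G, nu, C_I)
    if np.any(arg <= 0.0):
        raise ValueError("degenerate input: omega, u and nu all vanish")
    return arg**-0.5


def nu_c(G, tau):
    """Grad-div viscosity nu_C = 1/(tr(G) tau)."""
    tr = np.trace(np.asarray(G, dtype=np.float64), axis1=-2, axis2=-1)
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tr <= 0) or np.any(tau <= 0):
        raise ValueError("tr(G) and tau must be positive")
    return 1.0 / (tr * tau)


# ---------------------------------------------------------------------------
# global flow frequency


def _tri_quadrature(dim: int):
    """Degree-2 exact quadrature on the unit simplex: (weights, barycentric)."""
    if dim == 2:
        pts = np.array([[2 / 3, 1 / 6, 1 / 6],
                        [1 / 6, 2 / 3, 1 / 6],
                        [1 / 6, 1 / 6, 2 / 3]])
        w = np.full(3, 1 / 3)
    else:
        a, b = 0.5854101966249685, 0.1381966011250105
        pts = np.full((4, 4), b)
        np.fill_diagonal(pts, a)
        w = np.full(4, 1 / 4)
    return w, pts


def l2_norm_field(f: np.ndarray, mesh: Mesh) -> float:
    """L2(Omega) norm of a P1 nodal field (scalar or vector).

    Uses the degree-2 Gauss rule (3-point triangle / 4-point tetrahedron),
    which integrates the square of a P1 field exactly.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim == 1:
        f = f[:, None]
    vol = element_volumes(mesh)
    fe = f[mesh.elements]  # (n_el, d+1, nc)
    w, bary = _tri_quadrature(mesh.dim)
    fgp = np.einsum("gb,ebc->egc", bary, fe)  # values at Gauss points
    sq = np.einsum("g,egc,egc->e", w, fgp, fgp)
    return float(np.sqrt(np.sum(vol * sq)))


def omega_global(u_field: np.ndarray, a_field: np.ndarray, mesh: Mesh,
                 settings: StabilizationSettings,
                 is_first_step: bool = False) -> float:
    """Global flow frequency omega = ||a||_L2 / ||u||_L2.

    Falls back to 2/dt on the first step or when ||u||_L2 < epsilon_u
    (the velocity field is initialized from zero in a typical run, which
    would otherwise divide by zero).
    """
    if is_first_step:
        return 2.0 / settings.dt
    un = l2_norm_field(u_field, mesh)
    if un < settings.epsilon_u:
        return 2.0 / settings.dt
    return l2_norm_field(a_field, mesh) / un


def omega_ale(u_field: np.ndarray, a_field: np.ndarray, motion: MeshMotion,
              mesh: Mesh, settings: StabilizationSettings,
              is_first_step: bool = False) -> float:
    """ALE flow frequency: acceleration at mesh nodes over ||u - u_mesh||.

    Subtracting the mesh velocity from the denominator makes omega Galilean
    invariant: adding the same uniform velocity to the flow and the mesh
    leaves it unchanged.  Falls back to 2/dt on the first step or when the
    relative velocity norm is below epsilon_u.
    """
    uhat = np.asarray(motion.mesh_velocity, dtype=np.float64)
    if uhat.shape != np.asarray(u_field).shape:
        raise ValueError("mesh velocity shape does not match the velocity field")
    if is_first_step:
        return 2.0 / settings.dt
    rel = np.asarray(u_field, dtype=np.float64) - uhat
    rn = l2_norm_field(rel, mesh)
    if rn < settings.epsilon_u:
        return 2.0 / settings.dt
    return l2_norm_field(a_field, mesh) / rn
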