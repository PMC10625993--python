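"""Derived quantities: pressure drop, surface forces, shedding statistics.

Force extraction follows the variationally consistent reaction approach:
the momentum residual (including stabilization terms) is assembled without
boundary-condition row replacement and summed over the wall patch nodes,
which for stabilized FEM is superconvergent compared to integrating the
elementwise-constant P1 traction.  A direct traction integration is also
provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import AssemblyContext, BCSet, FluidProperties, State, \
    assemble_residual
from .mesh import Mesh, element_volumes
from .stabilization import StabilizationSettings

__all__ = [
    "ForceSeries",
    "BulkStats",
    "PoiseuilleReference",
    "pressure_drop",
    "surface_force",
    "traction_force",
    "bulk_statistics",
    "dominant_frequency",
    "poiseuille_reference",
]


class InsufficientWindow(ValueError):
    """The statistics window is too short to resolve the shedding period."""


@dataclass
class ForceSeries:
    """Drag/lift time series on a patch (per unit depth in 2D)."""

    times: np.ndarray
    F_D: np.ndarray
    F_L: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.F_D = np.asarray(self.F_D, dtype=np.float64)
        self.F_L = np.asarray(self.F_L, dtype=np.float64)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.F_D)) and np.all(np.isfinite(self.F_L))):
            raise ValueError("force series contains non-finite values")


@dataclass
class BulkStats:
    """Window statistics of the force coefficients and Strouhal number."""

    Cd_mean: float
    Cd_rms_fluct: float
    Cl_mean: float
    Cl_rms_fluct: float
    St: float
    window: tuple[float, float]
    U_ref: float
    D_ref: float
    rho_ref: float

    def as_dict(self) -> dict:
        return {"Cd_mean": self.Cd_mean, "Cd_rms_fluct": self.Cd_rms_fluct,
                "Cl_mean": self.Cl_mean, "Cl_rms_fluct": self.Cl_rms_fluct,
                "St": self.St, "window": list(self.window)}


def _patch_average(mesh: Mesh, patch_name: str, nodal: np.ndarray) -> float:
    """Area-weighted average of a nodal scalar over a boundary patch."""
    patch = mesh.patch(patch_name)
    if patch.facets.size == 0:
        raise ValueError(f"patch {patch_name!r} is empty")
    area, _ = mesh.facet_areas_normals(patch)
    vals = nodal[patch.facets].mean(axis=1)  # P1 facet average is exact
    return float(np.sum(area * vals) / np.sum(area))


def pressure_drop(state: State, mesh: Mesh, inlet_patch: str = "inlet",
                  outlet_patch: str = "outlet") -> float:
    """Area-averaged inlet pressure minus area-averaged outlet pressure."""
    return _patch_average(mesh, inlet_patch, state.p) \
        - _patch_average(mesh, outlet_patch, state.p)


def surface_force(ctx: AssemblyContext, state: State, patch_name: str,
                  props: FluidProperties, bcs: BCSet | None = None,
                  settings: StabilizationSettings | None = None,
                  omega: float = 0.0) -> tuple[float, float]:
    """Force exerted by the fluid on a wall patch via consistent reactions.

    Assembles the full residual (Galerkin + stabilization, no Dirichlet row
    replacement, Neumann data excluded) and sums its rows over the patch's
    velocity dofs; the negative of that sum is the fluid-on-body force.
    Returns (F_D, F_L) = (x, y) components (x, z in 3D runs use components
    directly).
    """
    mesh = ctx.mesh
    d = ctx.dim
    body = BCSet(body_force=bcs.body_force if bcs is not None else None)
    R = assemble_residual(ctx, props, state.u, state.p, state.a, state.t,
                          body, settings, omega, apply_bc=False)
    nodes = np.unique(mesh.patch(patch_name).facets)
    rows = R.reshape(-1, d + 1)[nodes, :d]
    force = -rows.sum(axis=0)
    return float(force[0]), float(force[1])


def traction_force(mesh: Mesh, state: State, patch_name: str,
                   props: FluidProperties) -> tuple[float, float]:
    """Direct integration of the P1 stress traction over a patch (the
    independent cross-check for :func:`surface_force`)."""
    from .mesh import shape_gradients

    patch = mesh.patch(patch_name)
    _, grads = shape_gradients(mesh)
    # facet -> owning element
    owner = {}
    d = mesh.dim
    import itertools
    for e, el in enumerate(mesh.elements):
        for combo in itertools.combinations(range(d + 1), d):
            owner[tuple(sorted(el[list(combo)]))] = e
    area, normal = mesh.facet_areas_normals(patch)
    force = np.zeros(d)
    for f, ar, n in zip(patch.facets, area, normal):
        e = owner[tuple(sorted(f))]
        ue = state.u[mesh.elements[e]]
        grad_u = np.einsum("ai,aj->ij", ue, grads[e])
        sigma = -np.mean(state.p[f]) * np.eye(d) \
            + props.mu * (grad_u + grad_u.T)
        # force on the body: its outward normal is -n (n points out of fluid)
        force += ar * (sigma @ (-n))
    return float(force[0]), float(force[1])


def dominant_frequency(times: np.ndarray, signal: np.ndarray) -> float:
    """Dominant frequency of a uniformly sampled signal by periodogram with
    parabolic interpolation of the spectral peak."""
    dt = float(np.mean(np.diff(times)))
    x = signal - np.mean(signal)
    n = x.size
    n_pad = 8 * n  # zero-padding refines the spectral grid before the fit
    spec = np.abs(np.fft.rfft(x * np.hanning(n), n=n_pad)) ** 2
    freqs = np.fft.rfftfreq(n_pad, dt)
    k = int(np.argmax(spec[1:]) + 1)
    if 1 <= k < spec.size - 1:
        y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    return float((k + shift) * freqs[1])


def mean_crossing_frequency(times: np.ndarray, signal: np.ndarray) -> float:
    """Frequency from mean upward-crossing spacing (cross-check for the
    periodogram estimate)."""
    x = signal - np.mean(signal)
    up = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
    if up.size < 2:
        raise InsufficientWindow("fewer than two mean crossings in window")
    # linear interpolation of crossing times
    tc = times[up] - x[up] * (times[up + 1] - times[up]) / (x[up + 1] - x[up])
    return float(1.0 / np.mean(np.diff(tc)))


def bulk_statistics(series: ForceSeries, window: tuple[float, float],
                    U_ref: float, D_ref: float, rho_ref: float,
                    min_periods: float = 5.0,
                    integer_periods: bool = False) -> BulkStats:
    """Coefficient statistics and Strouhal number over a stationary window.

    C = F / (1/2 rho_ref U_ref^2 D_ref); fluctuation rms is taken about the
    window mean.  St = f_peak D_ref / U_ref with f_peak from the lift
    periodogram.  Raises InsufficientWindow if the window holds fewer than
    ``min_periods`` shedding periods.

    ``integer_periods`` trims the start of the window so it spans a whole
    number of shedding periods (estimated from the lift spectrum), removing
    the partial-period truncation bias of the mean/rms estimates — useful
    when comparing statistics across runs with different time step sizes.
    """
    t0, t1 = window
    if t0 < series.times[0] - 1e-12 or t1 > series.times[-1] + 1e-12:
        raise ValueError("window lies outside the series span")
    sel = (series.times >= t0) & (series.times <= t1)
    if np.count_nonzero(sel) < 8:
        raise InsufficientWindow("window contains too few samples")
    t = series.times[sel]
    q = 0.5 * rho_ref * U_ref**2 * D_ref
    cd = series.F_D[sel] / q
    cl = series.F_L[sel] / q
    f_peak = dominant_frequency(t, cl)
    if f_peak * (t1 - t0) < min_periods:
        raise InsufficientWindow(
            f"window holds {f_peak * (t1 - t0):.2f} shedding periods, "
            f"need >= {min_periods}")
    if integer_periods:
        n_per = np.floor((t1 - t0) * f_peak)
        t0 = t1 - n_per / f_peak
        sel = (series.times >= t0 - 1e-12) & (series.times <= t1 + 1e-12)
        t = series.times[sel]
        cd = series.F_D[sel] / q
        cl = series.F_L[sel] / q
        f_peak = dominant_frequency(t, cl)
    return BulkStats(
        Cd_mean=float(np.mean(cd)),
        Cd_rms_fluct=float(np.std(cd)),
        Cl_mean=float(np.mean(cl)),
        Cl_rms_fluct=float(np.std(cl)),
        St=float(f_peak * D_ref / U_ref),
        window=(float(t0), float(t1)),
        U_ref=U_ref, D_ref=D_ref, rho_ref=rho_ref)


@dataclass
class PoiseuilleReference:
    """Hagen-Poiseuille reference for the straight-pipe verification."""

    Q: float
    R: float
    L: float
    mu: float
    dP_ref: float
    Re: float
    u_mean: float
    CFL: float | None = None
    mean_dx: float | None = None


def poiseuille_reference(Q: float, R: float, L: float, mu: float, rho: float,
                         dt: float | None = None,
                         mesh: Mesh | None = None) -> PoiseuilleReference:
    """dP_ref = 8 mu L Q / (pi R^4); Re = rho (Q/(pi R^2)) (2R) / mu.

    If ``dt`` and ``mesh`` are given, also reports the advective CFL number
    u_mean dt / mean_dx with mean_dx the mean element size (cube/square root
    of the mean element measure).
    """
    if min(Q, R, L, mu, rho) <= 0:
        raise ValueError("all Poiseuille parameters must be positive")
    u_mean = Q / (np.pi * R**2)
    dp = 8.0 * mu * L * Q / (np.pi * R**4)
    re = rho * u_mean * 2.0 * R / mu
    cfl = mean_dx = None
    if dt is not None and mesh is not None:
        vol = element_volumes(mesh)
        mean_dx = float(np.mean(vol) ** (1.0 / mesh.dim))
        cfl = float(u_mean * dt / mean_dx)
    return PoiseuilleReference(Q, R, L, mu, dp, re, float(u_mean), cfl,
                               mean_dx)
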