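"""Simplex meshes for the canonical flow geometries.

Provides linear-simplex (3-node triangle / 4-node tetrahedron) meshes for a
2D rectangular channel, a 2D box with a square obstacle, and a 3D circular
pipe, together with the per-element covariant metric tensor used by the
stabilization parameters.

All generators are deterministic: the same arguments always produce the same
nodes and connectivity, bitwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoundaryPatch",
    "Mesh",
    "generate_channel_mesh_2d",
    "generate_obstacle_mesh_2d",
    "generate_pipe_mesh_3d",
    "perturb_interior_nodes",
    "compute_metric_tensors",
    "element_volumes",
    "shape_gradients",
]


@dataclass
class BoundaryPatch:
    """A named set of boundary facets with a boundary-condition role.

    Facets are stored outward-oriented: in 2D the edge (a, b) has outward
    normal (t_y, -t_x) with t = x_b - x_a; in 3D the triangle (a, b, c) has
    outward normal (x_b - x_a) x (x_c - x_a).
    """

    name: str
    facets: np.ndarray  # (n_facets, dim) node indices
    role: str = "dirichlet"  # dirichlet | neumann | no_penetration

    def __post_init__(self) -> None:
        self.facets = np.asarray(self.facets, dtype=np.int64)
        if self.role not in ("dirichlet", "neumann", "no_penetration"):
            raise ValueError(f"unknown patch role {self.role!r}")


@dataclass
class Mesh:
    """An unstructured simplex mesh with tagged boundary patches."""

    dim: int
    nodes: np.ndarray  # (n_nodes, dim)
    elements: np.ndarray  # (n_el, dim + 1)
    boundary_patches: dict[str, BoundaryPatch] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        if self.nodes.shape[1] != self.dim:
            raise ValueError("node coordinate dimension mismatch")
        if self.elements.shape[1] != self.dim + 1:
            raise ValueError("simplex connectivity must have dim+1 nodes")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_el(self) -> int:
        return self.elements.shape[0]

    def patch(self, name: str) -> BoundaryPatch:
        try:
            return self.boundary_patches[name]
        except KeyError:
            raise KeyError(
                f"no boundary patch {name!r}; have {sorted(self.boundary_patches)}"
            ) from None

    # -- geometry helpers -------------------------------------------------

    def facet_areas_normals(self, patch: BoundaryPatch | str):
        """Measure and outward unit normal of every facet of a patch."""
        if isinstance(patch, str):
            patch = self.patch(patch)
        x = self.nodes[patch.facets]  # (nf, dim, dim)
        if self.dim == 2:
            t = x[:, 1] - x[:, 0]
            length = np.linalg.norm(t, axis=1)
            normal = np.stack([t[:, 1], -t[:, 0]], axis=1) / length[:, None]
            return length, normal
        v1 = x[:, 1] - x[:, 0]
        v2 = x[:, 2] - x[:, 0]
        cr = np.cross(v1, v2)
        area2 = np.linalg.norm(cr, axis=1)
        return 0.5 * area2, cr / area2[:, None]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        vol = element_volumes(self)
        if np.any(vol <= 0):
            raise ValueError("mesh contains non-positive-volume elements")
        boundary = _boundary_facets(self.elements)
        tagged: dict[tuple, int] = {}
        for p in self.boundary_patches.values():
            for f in p.facets:
                key = tuple(sorted(int(i) for i in f))
                tagged[key] = tagged.get(key, 0) + 1
        keys = {tuple(sorted(int(i) for i in f)) for f in boundary}
        if set(tagged) != keys or any(v != 1 for v in tagged.values()):
            raise ValueError("boundary patches do not partition the boundary")


# ---------------------------------------------------------------------------
# element geometry


def element_volumes(mesh: Mesh) -> np.ndarray:
    """Signed measures (area / volume) of all elements."""
    x = mesh.nodes[mesh.elements]  # (n_el, d+1, d)
    e = x[:, 1:, :] - x[:, :1, :]  # (n_el, d, d) edge matrix
    det = np.linalg.det(e)
    fact = 2.0 if mesh.dim == 2 else 6.0
    return det / fact


def shape_gradients(mesh: Mesh):
    """Physical gradients of the P1 shape functions and element volumes.

    Returns (vol, grads) with grads of shape (n_el, dim+1, dim) such that
    grads[e, a] = grad N_a on element e (constant for affine simplices).
    """
    x = mesh.nodes[mesh.elements]
    e = x[:, 1:, :] - x[:, :1, :]  # rows are edge vectors x_a - x_0
    det = np.linalg.det(e)
    fact = 2.0 if mesh.dim == 2 else 6.0
    vol = det / fact
    # grad N_a (a >= 1) are the rows of inv(e)^T = inv(e.T)
    inv_t = np.linalg.inv(np.swapaxes(e, 1, 2))  # (n_el, d, d)
    grads = np.empty((mesh.n_el, mesh.dim + 1, mesh.dim))
    grads[:, 1:, :] = inv_t
    grads[:, 0, :] = -inv_t.sum(axis=1)
    return vol, grads


def compute_metric_tensors(mesh: Mesh) -> np.ndarray:
    """Covariant element metric G_ij = sum_k (dxi_k/dx_i)(dxi_k/dx_j).

    The parent element is the unit right simplex with local node 0 at the
    origin, so the rows of the inverse affine Jacobian are the physical
    gradients of the parent coordinates xi_k = N_k (k = 1..dim).  G is
    symmetric positive definite, constant per element, and scales as
    length^-2.  Note that G depends (mildly) on which local node of each
    element sits at the parent origin; the generators in this module use a
    fixed, reproducible local ordering.
    """
    vol, grads = shape_gradients(mesh)
    if np.any(vol <= 0):
        raise ValueError("degenerate element: non-positive volume")
    b = grads[:, 1:, :]  # (n_el, d, d), rows = grad xi_k
    return np.einsum("eki,ekj->eij", b, b)


# ---------------------------------------------------------------------------
# boundary extraction


def _facet_list(elements: np.ndarray):
    """All (element, local facet) node tuples for simplices."""
    n_loc = elements.shape[1]
    facets = []
    for combo in itertools.combinations(range(n_loc), n_loc - 1):
        facets.append(elements[:, list(combo)])
    return facets


def _boundary_facets(elements: np.ndarray) -> np.ndarray:
    """Facets that appear in exactly one element (unoriented)."""
    all_f = np.concatenate(_facet_list(elements), axis=0)
    key = np.sort(all_f, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return all_f[idx[counts == 1]]


def _orient_outward(mesh_nodes: np.ndarray, elements: np.ndarray,
                    facets: np.ndarray) -> np.ndarray:
    """Orient boundary facets so their normals point out of the domain."""
    dim = mesh_nodes.shape[1]
    # map facet -> owning element
    owner = {}
    key_of = lambda f: tuple(sorted(int(i) for i in f))
    facet_keys = {key_of(f) for f in facets}
    for e, el in enumerate(elements):
        for combo in itertools.combinations(range(dim + 1), dim):
            k = key_of(el[list(combo)])
            if k in facet_keys:
                owner[k] = e
    out = facets.copy()
    for i, f in enumerate(out):
        el = elements[owner[key_of(f)]]
        opp = [n for n in el if n not in f][0]
        x = mesh_nodes[f]
        if dim == 2:
            t = x[1] - x[0]
            normal = np.array([t[1], -t[0]])
        else:
            normal = np.cross(x[1] - x[0], x[2] - x[0])
        if normal @ (x.mean(axis=0) - mesh_nodes[opp]) < 0:
            out[i, -2], out[i, -1] = f[-1], f[-2]
    return out


def _make_patches(mesh_nodes, elements, classify, roles) -> dict[str, BoundaryPatch]:
    """Split the outward-oriented boundary into named patches.

    classify(centroid) -> patch name; roles: name -> role.
    """
    facets = _orient_outward(mesh_nodes, elements, _boundary_facets(elements))
    centroids = mesh_nodes[facets].mean(axis=1)
    names = [classify(c) for c in centroids]
    patches = {}
    for name in sorted(set(names)):
        sel = np.array([n == name for n in names])
        patches[name] = BoundaryPatch(name, facets[sel], roles.get(name, "dirichlet"))
    return patches


# ---------------------------------------------------------------------------
# generators


def _min_edge_per_node(mesh: Mesh) -> np.ndarray:
    """Length of the shortest incident edge of every node."""
    el, x = mesh.elements, mesh.nodes
    me = np.full(mesh.n_nodes, np.inf)
    for i, j in itertools.combinations(range(mesh.dim + 1), 2):
        d = np.linalg.norm(x[el[:, i]] - x[el[:, j]], axis=1)
        np.minimum.at(me, el[:, i], d)
        np.minimum.at(me, el[:, j], d)
    return me


def perturb_interior_nodes(mesh: Mesh, amplitude: float, seed: int = 0) -> Mesh:
    """Deterministically displace interior nodes by ``amplitude`` times the
    local minimum edge length (uniform in each coordinate).

    Structured grids admit special discretely divergence-free interpolants
    that generic unstructured meshes do not; this perturbation restores the
    irregularity of a real mesh while keeping generation reproducible.
    Boundary nodes are never moved.  If the displacement would invert an
    element it is halved (up to 8 times) until the mesh is valid.
    """
    if amplitude <= 0:
        return mesh
    boundary_nodes = np.unique(np.concatenate(
        [p.facets.ravel() for p in mesh.boundary_patches.values()]))
    interior = np.ones(mesh.n_nodes, dtype=bool)
    interior[boundary_nodes] = False
    me = _min_edge_per_node(mesh)
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-1.0, 1.0, size=mesh.nodes.shape)
    shift[~interior] = 0.0
    shift *= amplitude * me[:, None]
    base = mesh.nodes.copy()
    for _ in range(9):
        mesh.nodes = base + shift
        if element_volumes(mesh).min() > 0:
            return mesh
        shift *= 0.5
    mesh.nodes = base
    raise RuntimeError("node perturbation kept inverting elements")


def generate_channel_mesh_2d(length: float, height: float, nx: int, ny: int,
                             perturb: float = 0.0, seed: int = 0) -> Mesh:
    """Structured triangulation of a rectangular channel [0,L] x [0,H].

    Each of the nx x ny grid cells is split into two triangles.  Boundary
    patches: ``inlet`` (x=0), ``outlet`` (x=L), ``wall_bottom``, ``wall_top``.
    """
    if length <= 0 or height <= 0:
        raise ValueError("channel dimensions must be positive")
    if nx < 1 or ny < 1:
        raise ValueError("cell counts must be >= 1")
    x = np.linspace(0.0, length, nx + 1)
    y = np.linspace(0.0, height, ny + 1)
    mesh = _grid_to_mesh(x, y, hole=None,
                         patch_names=("inlet", "outlet", "wall_bottom",
                                      "wall_top"))
    return perturb_interior_nodes(mesh, perturb, seed)


def _grid_to_mesh(x, y, hole, patch_names, obstacle_name="obstacle") -> Mesh:
    nx, ny = len(x) - 1, len(y) - 1
    X, Y = np.meshgrid(x, y, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1)

    cell_mask = np.ones((nx, ny), dtype=bool)
    if hole is not None:
        (hx0, hx1), (hy0, hy1) = hole
        xc = 0.5 * (x[:-1] + x[1:])
        yc = 0.5 * (y[:-1] + y[1:])
        inx = (xc > hx0) & (xc < hx1)
        iny = (yc > hy0) & (yc < hy1)
        cell_mask[np.ix_(inx, iny)] = False

    i, j = np.nonzero(cell_mask)
    n00, n10 = nid[i, j], nid[i + 1, j]
    n11, n01 = nid[i + 1, j + 1], nid[i, j + 1]
    tri = np.concatenate(
        [np.stack([n00, n10, n11], axis=1), np.stack([n00, n11, n01], axis=1)]
    )

    # drop unused (interior-hole) nodes, renumber
    used = np.unique(tri)
    renum = -np.ones(nodes.shape[0], dtype=np.int64)
    renum[used] = np.arange(used.size)
    nodes = nodes[used]
    tri = renum[tri]

    L, H = x[-1], y[-1]
    tol = 1e-9 * max(L, H)
    inlet_n, outlet_n, bottom_n, top_n = patch_names

    def classify(c):
        if c[0] < tol:
            return inlet_n
        if c[0] > L - tol:
            return outlet_n
        if c[1] < tol:
            return bottom_n
        if c[1] > H - tol:
            return top_n
        return obstacle_name

    roles = {inlet_n: "dirichlet", outlet_n: "neumann",
             bottom_n: "dirichlet", top_n: "dirichlet",
             obstacle_name: "dirichlet"}
    patches = _make_patches(nodes, tri, classify, roles)
    return Mesh(2, nodes, tri, patches)


def _graded_points(a: float, b: float, h0: float, ratio: float,
                   h_max: float, from_start: bool,
                   near_cap: float | None = None,
                   near_dist: float = 0.0) -> np.ndarray:
    """1D points on [a, b], spacing h0 at the refined end growing by `ratio`.

    Within ``near_dist`` of the refined end the spacing is capped at
    ``near_cap`` (a resolved near/wake zone); beyond it the cap is
    ``h_max``.  Spacings are rescaled so the points exactly fill [a, b].
    """
    length = b - a
    if length <= h0:
        return np.array([a, b])
    spac, h, s = [], h0, 0.0
    while s < length:
        cap = near_cap if (near_cap is not None and s < near_dist) else h_max
        hh = min(h, cap)
        spac.append(hh)
        s += hh
        h *= ratio
    spac = np.array(spac) * (length / s)
    pts = a + np.concatenate([[0.0], np.cumsum(spac)])
    pts[-1] = b
    if not from_start:
        pts = (a + b) - pts[::-1]
    return pts


def generate_obstacle_mesh_2d(domain: tuple[float, float] = (29.2, 12.0),
                              square_side: float = 1.0,
                              square_center: tuple[float, float] = (5.0, 6.0),
                              target_h: float = 0.125,
                              growth: float = 1.2,
                              h_max: float | None = None,
                              wake_h: float | None = None,
                              wake_length: float = 0.0,
                              perturb: float = 0.0, seed: int = 0) -> Mesh:
    """Graded triangulation of a box with a square hole (bluff-body case).

    The grid conforms to the square: spacing is ``target_h`` on the obstacle
    faces and grows geometrically (factor ``growth``) into the far field, up
    to ``h_max``.  A resolved wake corridor can be requested with ``wake_h``
    (spacing cap) and ``wake_length`` (streamwise extent downstream of the
    square; the same cap is applied within one ``wake_length/4`` of the
    square in the cross-stream direction), keeping the vortex street on
    near-isotropic cells.  Patches: inlet (x=0), outlet (x=Lx), wall_bottom,
    wall_top, obstacle (the square perimeter).

    With the defaults the obstacle sits centered vertically, 5 length units
    downstream of the inlet, in a 29.2 x 12 box — the canonical vortex
    shedding benchmark layout.
    """
    Lx, Ly = domain
    D = square_side
    cx, cy = square_center
    x0, x1 = cx - D / 2, cx + D / 2
    y0, y1 = cy - D / 2, cy + D / 2
    if not (0 < x0 < x1 < Lx and 0 < y0 < y1 < Ly):
        raise ValueError("square must lie strictly inside the domain")
    if target_h <= 0:
        raise ValueError("target_h must be positive")
    if h_max is None:
        h_max = 8.0 * target_h

    n_side = max(2, int(round(D / target_h)))
    band = lambda a, b: np.linspace(a, b, n_side + 1)
    cross = wake_length / 4.0
    x = np.concatenate([
        _graded_points(0.0, x0, target_h, growth, h_max, from_start=False)[:-1],
        band(x0, x1)[:-1],
        _graded_points(x1, Lx, target_h, growth, h_max, from_start=True,
                       near_cap=wake_h, near_dist=wake_length),
    ])
    y = np.concatenate([
        _graded_points(0.0, y0, target_h, growth, h_max, from_start=False,
                       near_cap=wake_h, near_dist=cross)[:-1],
        band(y0, y1)[:-1],
        _graded_points(y1, Ly, target_h, growth, h_max, from_start=True,
                       near_cap=wake_h, near_dist=cross),
    ])
    mesh = _grid_to_mesh(x, y, hole=((x0, x1), (y0, y1)),
                         patch_names=("inlet", "outlet", "wall_bottom", "wall_top"))
    mesh.boundary_patches["wall_bottom"].role = "no_penetration"
    mesh.boundary_patches["wall_top"].role = "no_penetration"
    return perturb_interior_nodes(mesh, perturb, seed)


def _disk_points_tris(radius: float, n_rings: int, n_theta: int):
    """Polar fan-and-rings triangulation of a disk, deterministic."""
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        th = 2 * np.pi * np.arange(n_theta) / n_theta
        pts.append(np.stack([r * np.cos(th), r * np.sin(th)], axis=1))
    pts = np.concatenate(pts)

    def ring_id(k, j):
        return 1 + (k - 1) * n_theta + (j % n_theta)

    tris = []
    for j in range(n_theta):  # center fan
        tris.append([0, ring_id(1, j), ring_id(1, j + 1)])
    for k in range(1, n_rings):
        for j in range(n_theta):
            a, b = ring_id(k, j), ring_id(k, j + 1)
            c, d = ring_id(k + 1, j), ring_id(k + 1, j + 1)
            tris.append([a, c, d])
            tris.append([a, d, b])
    return pts, np.array(tris, dtype=np.int64)


def _split_prism(p) -> list[tuple[int, ...]]:
    """Split prism (p[0..2] bottom, p[3..5] top) into 3 tets, choosing quad
    diagonals through each face's smallest global node id so that adjacent
    prisms decompose compatibly."""
    orders = [
        (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
        (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
    ]
    best = min(orders, key=lambda o: p[o[0]])
    v = [p[i] for i in best]
    if min(v[1], v[5]) < min(v[2], v[4]):
        tets = [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]),
                (v[0], v[4], v[5], v[3])]
    else:
        tets = [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]),
                (v[0], v[4], v[5], v[3])]
    return tets


def generate_pipe_mesh_3d(radius: float, length: float, target_h: float,
                          axial_h: float | None = None,
                          perturb: float = 0.0, seed: int = 0) -> Mesh:
    """Tetrahedral mesh of a circular pipe along +z.

    A polar triangulation of the cross-section (center fan plus rings) is
    extruded into triangular prisms, each split into three tetrahedra with
    face-compatible diagonals.  Patches: ``inlet`` (z=0), ``outlet`` (z=L),
    ``wall`` (lateral surface).  ``axial_h`` decouples the axial spacing from
    the in-plane spacing (defaults to ``target_h``).
    """
    if radius <= 0 or length <= 0 or target_h <= 0:
        raise ValueError("radius, length and target_h must be positive")
    if axial_h is None:
        axial_h = target_h
    n_rings = max(2, int(round(radius / target_h)))
    n_theta = max(8, 4 * int(round(np.pi * n_rings / 2)))
    n_layers = max(2, int(round(length / axial_h)))

    pts2d, tris2d = _disk_points_tris(radius, n_rings, n_theta)
    n2d = pts2d.shape[0]
    z = np.linspace(0.0, length, n_layers + 1)
    nodes = np.concatenate(
        [np.column_stack([pts2d, np.full(n2d, zz)]) for zz in z]
    )
    tets = []
    for layer in range(n_layers):
        lo, hi = layer * n2d, (layer + 1) * n2d
        for t in tris2d:
            prism = (lo + t[0], lo + t[1], lo + t[2],
                     hi + t[0], hi + t[1], hi + t[2])
            tets.extend(_split_prism(prism))
    tets = np.array(tets, dtype=np.int64)

    # enforce positive orientation (split rule fixes geometry, not sign)
    x = nodes[tets]
    det = np.linalg.det(x[:, 1:, :] - x[:, :1, :])
    flip = det < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    if np.any(np.abs(det) < 1e-14 * target_h**3):
        raise RuntimeError("pipe mesh generation produced degenerate tetrahedra")

    tol = 1e-9 * max(radius, length)

    def classify(c):
        if c[2] < tol:
            return "inlet"
        if c[2] > length - tol:
            return "outlet"
        return "wall"

    roles = {"inlet": "dirichlet", "outlet": "neumann", "wall": "dirichlet"}
    patches = _make_patches(nodes, tets, classify, roles)
    return perturb_interior_nodes(Mesh(3, nodes, tets, patches), perturb, seed)
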