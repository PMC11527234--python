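"""Synthetic peritoneal-cavity and channel geometry.

Patient-specific peritoneal segmentations are rarely shareable, so this
module generates *synthetic* cavity meshes: a
box-like fluid domain of ascites-scale volume with a deformable top
("diaphragm"), fixed lateral and floor walls, and two spherical-cap "ovary"
protrusions on the floor.  A planar (x, z) cross-section mode with
circular-arc ovary bumps is a first-class citizen for desk-scale runs.

Coordinate convention: ``z`` is the cranio-caudal axis, ``z = cavity_height``
at the diaphragm.  All lengths are SI metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

CAVITY_PATCHES = ("diaphragm", "lateral", "floor", "ovary_left", "ovary_right")


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Unstructured simplex mesh with labelled boundary patches.

    Attributes
    ----------
    points : (n_nodes, dim) float array of vertex coordinates in metres.
    cells : (n_cells, dim+1) int connectivity, positively oriented.
    boundary_facets : (n_facets, dim) int connectivity of boundary facets,
        oriented so the induced normal points out of the fluid.
    facet_patches : (n_facets,) array of patch names, one per facet.
    dim : spatial dimension (2 or 3).
    """

    points: np.ndarray
    cells: np.ndarray
    boundary_facets: np.ndarray
    facet_patches: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.boundary_facets = np.ascontiguousarray(
            self.boundary_facets, dtype=np.int64
        )
        self.facet_patches = np.asarray(self.facet_patches)

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def patch_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.facet_patches.tolist())))

    def facets_of(self, patch: str) -> np.ndarray:
        """Indices into ``boundary_facets`` belonging to ``patch``."""
        idx = np.nonzero(self.facet_patches == patch)[0]
        if idx.size == 0:
            raise KeyError(
                f"patch {patch!r} not present; available: {self.patch_names}"
            )
        return idx

    def boundary_node_ids(self, patch: str | None = None) -> np.ndarray:
        """Sorted unique vertex ids on the boundary (optionally one patch)."""
        if patch is None:
            facets = self.boundary_facets
        else:
            facets = self.boundary_facets[self.facets_of(patch)]
        return np.unique(facets)

    # -- geometry -----------------------------------------------------------

    def cell_volumes(self) -> np.ndarray:
        return _signed_simplex_volumes(self.points, self.cells)

    def facet_areas(self) -> np.ndarray:
        return _facet_areas(self.points, self.boundary_facets)

    def facet_normals(self) -> np.ndarray:
        """Outward unit normals of boundary facets (relies on orientation)."""
        return _facet_normals(self.points, self.boundary_facets)

    def facet_centroids(self) -> np.ndarray:
        return self.points[self.boundary_facets].mean(axis=1)

    def displaced(self, displacement: np.ndarray) -> "Mesh":
        """Copy of the mesh with vertex coordinates moved by ``displacement``."""
        disp = np.asarray(displacement, dtype=float)
        if disp.shape != self.points.shape:
            raise ValueError(
                f"displacement shape {disp.shape} != points {self.points.shape}"
            )
        return Mesh(
            self.points + disp,
            self.cells,
            self.boundary_facets,
            self.facet_patches,
            self.dim,
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` on inverted cells or an inconsistent boundary."""
        vols = self.cell_volumes()
        bad = np.nonzero(vols <= 0.0)[0]
        if bad.size:
            raise ValueError(
                f"{bad.size} non-positive cell volumes; first offenders: "
                f"{bad[:10].tolist()}"
            )
        areas = self.facet_areas()
        if np.any(areas <= 0.0):
            raise ValueError("boundary facets with zero area present")
        # the labelled facets must be exactly the topological boundary
        topo = boundary_faces(self.cells)
        key_topo = {tuple(sorted(f)) for f in topo}
        key_lab = [tuple(sorted(f)) for f in self.boundary_facets]
        if len(key_lab) != len(set(key_lab)):
            raise ValueError("duplicate boundary facet labels")
        if set(key_lab) != key_topo:
            raise ValueError(
                "labelled boundary facets do not cover the topological boundary"
            )


# ---------------------------------------------------------------------------
# low-level simplex utilities
# ---------------------------------------------------------------------------


def _signed_simplex_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    p = points[cells]
    if cells.shape[1] == 3:
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    e3 = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0


def _facet_areas(points: np.ndarray, facets: np.ndarray) -> np.ndarray:
    p = points[facets]
    if facets.shape[1] == 2:
        return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def _facet_normals(points: np.ndarray, facets: np.ndarray) -> np.ndarray:
    p = points[facets]
    if facets.shape[1] == 2:
        t = p[:, 1] - p[:, 0]
        n = np.stack([t[:, 1], -t[:, 0]], axis=1)
    else:
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def boundary_faces(cells: np.ndarray) -> np.ndarray:
    """Unordered facets that belong to exactly one cell."""
    nv = cells.shape[1]
    if nv == 3:
        local = [(0, 1), (1, 2), (2, 0)]
    else:
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([cells[:, idx] for idx in local], axis=0)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _orient_cells(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    vols = _signed_simplex_volumes(points, cells)
    flip = vols < 0
    cells = cells.copy()
    cells[flip, 0], cells[flip, 1] = cells[flip, 1], cells[flip, 0].copy()
    return cells


def _orient_boundary_outward(
    points: np.ndarray, cells: np.ndarray, facets: np.ndarray
) -> np.ndarray:
    """Flip facets whose normal points into the domain.

    Each boundary facet is matched to its owning cell; the normal must point
    away from the cell's remaining vertex (2D) / vertex opposite the face (3D).
    """
    nv = cells.shape[1]
    facets = facets.copy()
    if nv == 3:
        local = [(0, 1), (1, 2), (2, 0)]
    else:
        local = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    all_faces = np.concatenate([cells[:, idx] for idx in local], axis=0)
    owners = np.tile(np.arange(cells.shape[0]), len(local))
    keys = [tuple(k) for k in np.sort(all_faces, axis=1)]
    owner_of = {}
    for k, o in zip(keys, owners):
        owner_of.setdefault(k, []).append(o)
    normals = _facet_normals(points, facets)
    centroids = points[facets].mean(axis=1)
    for i, f in enumerate(facets):
        k = tuple(sorted(f))
        owner = owner_of[k][0]
        opposite = [v for v in cells[owner] if v not in f]
        ref = points[opposite].mean(axis=0)
        if np.dot(normals[i], centroids[i] - ref) < 0:
            facets[i, 0], facets[i, 1] = facets[i, 1], facets[i, 0]
    return facets


def graded_points(a: float, b: float, n: int, cluster: float = 1.0,
                  side: str = "both") -> np.ndarray:
    """``n+1`` points on [a, b]; ``cluster`` > 1 packs points near walls.

    ``side``: "both" (tanh symmetric), "start", "end", or "none".
    """
    s = np.linspace(0.0, 1.0, n + 1)
    if cluster > 1.0:
        if side == "both":
            s = 0.5 * (1.0 + np.tanh(cluster * (2 * s - 1)) / np.tanh(cluster))
        elif side == "start":
            s = 1.0 + np.tanh(cluster * (s - 1)) / np.tanh(cluster)
        elif side == "end":
            s = np.tanh(cluster * s) / np.tanh(cluster)
    return a + (b - a) * s


# ---------------------------------------------------------------------------
# structured generators
# ---------------------------------------------------------------------------


def structured_rectangle(
    x: np.ndarray,
    z_hat: np.ndarray,
    floor_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    patch_fn: Callable[[str, np.ndarray], str] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> Mesh:
    """Crossed-triangle mesh of a rectangle, optionally with a curved floor.

    Every grid quad is split into 4 triangles around its centre node, which
    keeps the mesh exactly mirror-symmetric for a symmetric ``x`` grid.  A
    ``floor_profile`` p(x) remaps z from [0, H] to [p(x), H], producing wall
    bumps (ovaries, idealized cells) without unstructured meshing.
    """
    x = np.asarray(x, float)
    z_hat = np.asarray(z_hat, float)
    nx, nz = len(x) - 1, len(z_hat) - 1
    H = z_hat[-1]

    def zmap(xv: np.ndarray, zh: np.ndarray) -> np.ndarray:
        if floor_profile is None:
            return zh
        p = floor_profile(np.atleast_1d(xv))
        return p + zh * (H - p) / H

    gx, gz = np.meshgrid(x, z_hat, indexing="ij")
    grid_pts = np.stack([gx.ravel(), zmap(gx.ravel(), gz.ravel())], axis=1)

    xc = 0.5 * (x[:-1] + x[1:])
    zc = 0.5 * (z_hat[:-1] + z_hat[1:])
    gxc, gzc = np.meshgrid(xc, zc, indexing="ij")
    centre_pts = np.stack([gxc.ravel(), zmap(gxc.ravel(), gzc.ravel())], axis=1)

    points = np.vstack([grid_pts, centre_pts])
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        dx = np.min(np.diff(x))
        interior = np.zeros(len(points), bool)
        gi = np.arange((nx + 1) * (nz + 1)).reshape(nx + 1, nz + 1)
        interior[gi[1:-1, 1:-1].ravel()] = True
        points[interior] += jitter * dx * rng.uniform(-1, 1, (interior.sum(), 2))

    def vid(i, j):
        return i * (nz + 1) + j

    def cid(i, j):
        return (nx + 1) * (nz + 1) + i * nz + j

    cells = []
    for i in range(nx):
        for j in range(nz):
            c = cid(i, j)
            v00, v10 = vid(i, j), vid(i + 1, j)
            v11, v01 = vid(i + 1, j + 1), vid(i, j + 1)
            cells += [[v00, v10, c], [v10, v11, c], [v11, v01, c], [v01, v00, c]]
    cells = _orient_cells(points, np.array(cells, np.int64))

    facets, patches = [], []
    if patch_fn is None:
        patch_fn = _default_rect_patches
    for i in range(nx):  # bottom, +x traversal -> outward normal (0,-1)-ish
        facets.append([vid(i, 0), vid(i + 1, 0)])
        patches.append(patch_fn("floor", points[facets[-1]].mean(axis=0)))
    for j in range(nz):  # right, +z
        facets.append([vid(nx, j), vid(nx, j + 1)])
        patches.append(patch_fn("right", points[facets[-1]].mean(axis=0)))
    for i in range(nx - 1, -1, -1):  # top, -x
        facets.append([vid(i + 1, nz), vid(i, nz)])
        patches.append(patch_fn("top", points[facets[-1]].mean(axis=0)))
    for j in range(nz - 1, -1, -1):  # left, -z
        facets.append([vid(0, j + 1), vid(0, j)])
        patches.append(patch_fn("left", points[facets[-1]].mean(axis=0)))

    mesh = Mesh(points, cells, np.array(facets, np.int64), np.array(patches), 2)
    mesh.validate()
    return mesh


def _default_rect_patches(side: str, mid: np.ndarray) -> str:
    return {"floor": "floor", "right": "right", "top": "top", "left": "left"}[side]


def structured_box(
    x: np.ndarray,
    y: np.ndarray,
    z_hat: np.ndarray,
    floor_profile: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    patch_fn: Callable[[np.ndarray], str] | None = None,
) -> Mesh:
    """Tetrahedral mesh of a box (6 tets per hex), optional curved floor."""
    x, y, z_hat = (np.asarray(a, float) for a in (x, y, z_hat))
    nx, ny, nz = len(x) - 1, len(y) - 1, len(z_hat) - 1
    H = z_hat[-1]
    gx, gy, gz = np.meshgrid(x, y, z_hat, indexing="ij")
    X, Y, Z = gx.ravel(), gy.ravel(), gz.ravel()
    if floor_profile is not None:
        p = floor_profile(X, Y)
        Z = p + Z * (H - p) / H
    points = np.stack([X, Y, Z], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    v = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                v[(di, dj, dk)] = vid(I + di, J + dj, K + dk)
    # six tets sharing the (0,0,0)-(1,1,1) diagonal
    tet_corners = [
        ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
        ((0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)),
        ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
        ((0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)),
        ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
        ((0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1)),
    ]
    cells = np.concatenate(
        [np.stack([v[a], v[b], v[c], v[d]], axis=1) for a, b, c, d in tet_corners]
    )
    cells = _orient_cells(points, cells)

    facets = boundary_faces(cells)
    facets = _orient_boundary_outward(points, cells, facets)
    if patch_fn is None:
        patch_fn = lambda mid: "wall"  # noqa: E731
    mids = points[facets].mean(axis=1)
    patches = np.array([patch_fn(m) for m in mids])
    mesh = Mesh(points, cells, facets, patches, 3)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# cavity specification and builder
# ---------------------------------------------------------------------------


@dataclass
class CavitySpec:
    """Parameters of the synthetic ascites cavity.

    Either give explicit ``cavity_width/depth/height`` or a ``target_volume``
    (the realized mesh volume then lands within 2% of it) with aspect ratios
    width:height and depth:height.  Ovaries are spherical caps protruding from
    the floor; ``z_ov`` is the reference height below which the wall is held
    stationary by the breathing kinematics.
    """

    cavity_height: float = 0.40
    cavity_width: float = 0.30
    cavity_depth: float = 0.20
    target_volume: float | None = None
    aspect_width: float = 1.2
    aspect_depth: float = 0.8
    ovary_radius: float = 0.03
    ovary_centers: tuple = ((-0.08, 0.0, -0.005), (0.08, 0.0, -0.005))
    z_ov: float = 0.04
    mesh_size: float = 0.01
    refinement_level: int = 0
    dim: int = 2
    wall_grading: float = 1.0  # > 1 packs layers toward floor and diaphragm
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_volume is not None:
            if self.target_volume <= 0:
                raise ValueError("target_volume must be positive")
            caps = sum(_cap_volume(self.ovary_radius, c[2]) for c in self.ovary_centers)
            h = ((self.target_volume + caps) / (self.aspect_width * self.aspect_depth)) ** (1.0 / 3.0)
            self.cavity_height = h
            self.cavity_width = self.aspect_width * h
            self.cavity_depth = self.aspect_depth * h
        for name in ("cavity_height", "cavity_width", "cavity_depth",
                     "ovary_radius", "mesh_size", "z_ov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.refinement_level < 0:
            raise ValueError("refinement_level must be >= 0")
        if self.z_ov > self.cavity_height:
            raise ValueError("z_ov exceeds cavity_height")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        for c in self.ovary_centers:
            if len(c) != 3:
                raise ValueError("ovary_centers must be 3-vectors")
            if not (-self.ovary_radius < c[2] <= 0.0):
                raise ValueError(
                    "ovary sphere must protrude through the floor: require "
                    f"-radius < center_z <= 0, got center_z={c[2]}"
                )
        if len(self.ovary_centers) != 2:
            raise ValueError("exactly two ovary centers required")

    def floor_profile_2d(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        p = np.zeros_like(x)
        r = self.ovary_radius
        for cx, _, cz in self.ovary_centers:
            d2 = r * r - (x - cx) ** 2
            bump = np.where(d2 > 0, np.sqrt(np.maximum(d2, 0.0)) + cz, 0.0)
            p = np.maximum(p, np.maximum(bump, 0.0))
        return p

    def floor_profile_3d(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        p = np.zeros_like(x)
        r = self.ovary_radius
        for cx, cy, cz in self.ovary_centers:
            d2 = r * r - (x - cx) ** 2 - (y - cy) ** 2
            bump = np.where(d2 > 0, np.sqrt(np.maximum(d2, 0.0)) + cz, 0.0)
            p = np.maximum(p, np.maximum(bump, 0.0))
        return p


def _cap_volume(r: float, cz: float) -> float:
    """Volume of the spherical cap of radius ``r`` centred at z=cz (< 0)."""
    h = r + cz
    return np.pi * h * h * (3 * r - h) / 3.0


def build_cavity_mesh(spec: CavitySpec) -> Mesh:
    """Generate the synthetic cavity mesh with the five standard patches.

    Deterministic for fixed (spec, seed).  In 2D the ovaries are circular-arc
    floor bumps in the vertical mid-plane; in 3D they are spherical caps.
    """
    h = spec.mesh_size / (2 ** spec.refinement_level)
    W, H = spec.cavity_width, spec.cavity_height
    tol = 1e-12

    def patch_fn_2d(side: str, mid: np.ndarray) -> str:
        if side == "top":
            return "diaphragm"
        if side in ("left", "right"):
            return "lateral"
        if spec.floor_profile_2d(mid[0])[0] > tol:
            return "ovary_left" if mid[0] < 0 else "ovary_right"
        return "floor"

    if spec.dim == 2:
        nx = max(8, int(round(W / h)))
        nz = max(4, int(round(H / h)))
        if nx % 2:
            nx += 1  # keep the grid mirror-symmetric about x = 0
        x = np.linspace(-W / 2, W / 2, nx + 1)
        z = graded_points(0.0, H, nz, cluster=spec.wall_grading, side="both")
        return structured_rectangle(
            x, z, spec.floor_profile_2d, patch_fn_2d,
            jitter=spec.jitter, seed=spec.seed,
        )

    D = spec.cavity_depth

    def patch_fn_3d(mid: np.ndarray) -> str:
        if abs(mid[2] - H) < 1e-6 * H:
            return "diaphragm"
        if (abs(abs(mid[0]) - W / 2) < 1e-6 * W
                or abs(abs(mid[1]) - D / 2) < 1e-6 * D):
            return "lateral"
        if spec.floor_profile_3d(mid[0], mid[1])[0] > tol:
            return "ovary_left" if mid[0] < 0 else "ovary_right"
        return "floor"

    nx = max(6, int(round(W / h)))
    ny = max(6, int(round(D / h)))
    nz = max(4, int(round(H / h)))
    if nx % 2:
        nx += 1
    x = np.linspace(-W / 2, W / 2, nx + 1)
    y = np.linspace(-D / 2, D / 2, ny + 1)
    z = graded_points(0.0, H, nz, cluster=spec.wall_grading, side="both")
    return structured_box(x, y, z, spec.floor_profile_3d, patch_fn_3d)


# ---------------------------------------------------------------------------
# mesh operations
# ---------------------------------------------------------------------------


def compute_volume(mesh: Mesh) -> float:
    """Total mesh volume (area in 2D); raises on inverted cells."""
    vols = _signed_simplex_volumes(mesh.points, mesh.cells)
    bad = np.nonzero(vols <= 0)[0]
    if bad.size:
        raise ValueError(
            f"inverted cells detected: {bad[:20].tolist()}"
            + ("..." if bad.size > 20 else "")
        )
    return float(vols.sum())


def enclosed_volume(points: np.ndarray, facets: np.ndarray, dim: int) -> float:
    """Volume enclosed by an oriented boundary, via the divergence theorem.

    Exact for straight facets; needs only boundary nodes, which makes it the
    cheap objective for the isovolumetric compensation root-find.
    """
    p = points[facets]
    centroids = p.mean(axis=1)
    if dim == 2:
        t = p[:, 1] - p[:, 0]
        n = np.stack([t[:, 1], -t[:, 0]], axis=1)  # length-weighted normal
        return float(np.einsum("ij,ij->", centroids, n) / 2.0)
    n = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
    return float(np.einsum("ij,ij->", centroids, n) / 3.0)


def refine(mesh: Mesh, levels: int = 1) -> Mesh:
    """Uniform red refinement; patch labels inherited by child facets."""
    if levels < 0:
        raise ValueError("levels must be >= 0")
    out = mesh
    for _ in range(levels):
        out = _refine_once(out)
    return out


def _refine_once(mesh: Mesh) -> Mesh:
    cells = mesh.cells
    nv = mesh.n_nodes
    if mesh.dim == 2:
        pairs = np.concatenate([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    else:
        pairs = np.concatenate([
            cells[:, [0, 1]], cells[:, [0, 2]], cells[:, [0, 3]],
            cells[:, [1, 2]], cells[:, [1, 3]], cells[:, [2, 3]],
        ])
    key = np.sort(pairs, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid_ids = nv + np.arange(len(uniq))
    points = np.vstack([mesh.points, mesh.points[uniq].mean(axis=1)])

    def mid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        k = np.sort(np.stack([a, b], axis=1), axis=1)
        # locate rows of k in uniq via void view
        dt = np.dtype((np.void, uniq.dtype.itemsize * uniq.shape[1]))
        uview = np.ascontiguousarray(uniq).view(dt).ravel()
        kview = np.ascontiguousarray(k).view(dt).ravel()
        order = np.argsort(uview)
        pos = order[np.searchsorted(uview[order], kview)]
        return mid_ids[pos]

    if mesh.dim == 2:
        a, b, c = cells[:, 0], cells[:, 1], cells[:, 2]
        mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
        new_cells = np.concatenate([
            np.stack([a, mab, mca], axis=1),
            np.stack([mab, b, mbc], axis=1),
            np.stack([mca, mbc, c], axis=1),
            np.stack([mab, mbc, mca], axis=1),
        ])
        fa, fb = mesh.boundary_facets[:, 0], mesh.boundary_facets[:, 1]
        fm = mid(fa, fb)
        new_facets = np.concatenate([
            np.stack([fa, fm], axis=1), np.stack([fm, fb], axis=1)
        ])
        new_patches = np.concatenate([mesh.facet_patches, mesh.facet_patches])
    else:
        v0, v1, v2, v3 = (cells[:, i] for i in range(4))
        m01, m02, m03 = mid(v0, v1), mid(v0, v2), mid(v0, v3)
        m12, m13, m23 = mid(v1, v2), mid(v1, v3), mid(v2, v3)
        new_cells = np.concatenate([
            np.stack([v0, m01, m02, m03], axis=1),
            np.stack([v1, m01, m12, m13], axis=1),
            np.stack([v2, m02, m12, m23], axis=1),
            np.stack([v3, m03, m13, m23], axis=1),
            np.stack([m01, m02, m03, m13], axis=1),
            np.stack([m01, m02, m12, m13], axis=1),
            np.stack([m02, m03, m13, m23], axis=1),
            np.stack([m02, m12, m13, m23], axis=1),
        ])
        new_cells = _orient_cells(points, new_cells)
        fa, fb, fc = (mesh.boundary_facets[:, i] for i in range(3))
        mab, mbc, mca = mid(fa, fb), mid(fb, fc), mid(fc, fa)
        new_facets = np.concatenate([
            np.stack([fa, mab, mca], axis=1),
            np.stack([mab, fb, mbc], axis=1),
            np.stack([mca, mbc, fc], axis=1),
            np.stack([mab, mbc, mca], axis=1),
        ])
        new_patches = np.concatenate([mesh.facet_patches] * 4)
    out = Mesh(points, new_cells, new_facets, new_patches, mesh.dim)
    out.validate()
    return out


@dataclass
class QualityReport:
    min_cell_volume: float
    max_aspect_ratio: float
    min_aspect_ratio: float
    n_nodes: int
    n_cells: int
    boundary_area_by_patch: dict

    def total_boundary_area(self) -> float:
        return float(sum(self.boundary_area_by_patch.values()))


def quality_report(mesh: Mesh) -> QualityReport:
    """Cell-quality and patch-area summary; validates the mesh first."""
    mesh.validate()
    vols = mesh.cell_volumes()
    p = mesh.points[mesh.cells]
    nvert = mesh.cells.shape[1]
    edges = []
    for i in range(nvert):
        for j in range(i + 1, nvert):
            edges.append(np.linalg.norm(p[:, i] - p[:, j], axis=1))
    edges = np.stack(edges, axis=1)
    aspect = edges.max(axis=1) / edges.min(axis=1)
    areas = mesh.facet_areas()
    by_patch = {
        name: float(areas[mesh.facet_patches == name].sum())
        for name in mesh.patch_names
    }
    return QualityReport(
        min_cell_volume=float(vols.min()),
        max_aspect_ratio=float(aspect.max()),
        min_aspect_ratio=float(aspect.min()),
        n_nodes=mesh.n_nodes,
        n_cells=mesh.n_cells,
        boundary_area_by_patch=by_patch,
    )


def min_cell_diameter(mesh: Mesh) -> float:
    p = mesh.points[mesh.cells]
    nvert = mesh.cells.shape[1]
    dmin = np.inf
    for i in range(nvert):
        for j in range(i + 1, nvert):
            dmin = min(dmin, float(np.linalg.norm(p[:, i] - p[:, j], axis=1).min()))
    return dmin


# ---------------------------------------------------------------------------
# verification / bioreactor geometries
# ---------------------------------------------------------------------------


def build_channel_mesh(
    length: float,
    height: float,
    nx: int,
    ny: int,
    floor_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    bump_patch: str = "cell",
    x_grid: np.ndarray | None = None,
    y_cluster: float = 1.0,
) -> Mesh:
    """Straight channel [0, L] x [0, h]; optional floor bump patch.

    Patches: ``inlet`` (x=0), ``outlet`` (x=L), ``top``, ``floor``, and
    ``bump_patch`` wherever the floor profile is raised.  ``y_cluster`` > 1
    packs points toward both walls (oscillatory boundary layers).
    """
    x = np.linspace(0.0, length, nx + 1) if x_grid is None else np.asarray(x_grid)
    y = graded_points(0.0, height, ny, cluster=y_cluster, side="both")

    def patch_fn(side: str, mid: np.ndarray) -> str:
        if side == "left":
            return "inlet"
        if side == "right":
            return "outlet"
        if side == "top":
            return "top"
        if floor_profile is not None and floor_profile(mid[:1])[0] > 1e-14:
            return bump_patch
        return "floor"

    return structured_rectangle(x, y, floor_profile, patch_fn)


def build_shell_mesh(
    radius: float,
    outer_radius: float,
    n_theta: int = 48,
    n_r: int = 16,
    grading: float = 1.0,
) -> Mesh:
    """Half spherical shell in the (r, z) meridian plane for axisymmetric flow.

    The domain is {a <= |x| <= R, r_cyl >= 0}; patches: ``sphere`` (inner),
    ``outer``, ``axis`` (the two segments on r_cyl = 0).  ``grading`` > 1
    packs radial layers toward the sphere.
    """
    theta = np.linspace(0.0, np.pi, n_theta + 1)
    s = np.linspace(0.0, 1.0, n_r + 1) ** grading
    rad = radius + (outer_radius - radius) * s

    gt, gr = np.meshgrid(theta, rad, indexing="ij")
    grid = np.stack([(gr * np.sin(gt)).ravel(), (gr * np.cos(gt)).ravel()], axis=1)
    tc = 0.5 * (theta[:-1] + theta[1:])
    rc = 0.5 * (rad[:-1] + rad[1:])
    gtc, grc = np.meshgrid(tc, rc, indexing="ij")
    centre = np.stack([(grc * np.sin(gtc)).ravel(), (grc * np.cos(gtc)).ravel()],
                      axis=1)
    points = np.vstack([grid, centre])

    nt, nr = n_theta, n_r

    def vid(i, j):
        return i * (nr + 1) + j

    def cid(i, j):
        return (nt + 1) * (nr + 1) + i * nr + j

    cells = []
    for i in range(nt):
        for j in range(nr):
            c = cid(i, j)
            v00, v10 = vid(i, j), vid(i + 1, j)
            v11, v01 = vid(i + 1, j + 1), vid(i, j + 1)
            cells += [[v00, v10, c], [v10, v11, c], [v11, v01, c], [v01, v00, c]]
    cells = _orient_cells(points, np.array(cells, np.int64))

    facets = boundary_faces(cells)
    facets = _orient_boundary_outward(points, cells, facets)
    mids = points[facets].mean(axis=1)
    rr = np.linalg.norm(mids, axis=1)
    # classify by distance to the inner vs outer radius; axis facets by r ~ 0
    patches = np.where(mids[:, 0] < 1e-9 * outer_radius, "axis",
                       np.where(np.abs(rr - radius) < np.abs(rr - outer_radius),
                                "sphere", "outer"))
    mesh = Mesh(points, cells, facets, np.asarray(patches, dtype="U8"), 2)
    mesh.validate()
    return mesh
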