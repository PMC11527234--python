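"""Breathing-driven boundary kinematics of the ascites cavity.

The diaphragm patch (cavity top) is prescribed a vertical excursion whose
amplitude decays linearly from the top of the ascites (maximum) down to the
ovary reference height ``z_ov`` (zero); everything at or below ``z_ov`` is
held stationary.  Because the cavity is closed and the fluid incompressible,
the prescribed motion must preserve the enclosed volume: a spatially uniform
outward/inward normal displacement (weighted by the same vertical profile) is
added on the lateral walls, with its magnitude solved by 1D root-finding so
that the enclosed volume matches the rest volume to 0.1% or better.

The boundary field is propagated into the mesh interior with a linear
elastic (pseudo-solid) solve with Dirichlet data on the whole boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.linalg import splu

from .geometry import Mesh, enclosed_volume

# Breathing parameter pairs: maximum diaphragm excursion (m) and frequency
# (Hz) for quiet ("regular") and energetic ("active") respiration.
PRESET_TABLE = {
    "regular": (0.060, 0.37),
    "active": (0.080, 1.0),
}


@dataclass(frozen=True)
class BreathingPreset:
    """Diaphragm forcing: excursion amplitude (m), frequency (Hz), cycles."""

    amplitude: float
    frequency: float
    n_cycles: int = 3
    waveform: str = "raised_cosine"
    direction: float = -1.0  # -1: excursion compresses the cavity (downward)

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.frequency <= 0:
            raise ValueError("amplitude and frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.waveform not in ("raised_cosine", "sine"):
            raise ValueError("waveform must be 'raised_cosine' or 'sine'")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def shape(self, t: float | np.ndarray) -> float | np.ndarray:
        """Dimensionless time profile s(t); raised cosine has s(0) = 0 and
        zero initial velocity, so the fluid can start from rest."""
        w = 2.0 * np.pi * self.frequency * np.asarray(t, float)
        if self.waveform == "raised_cosine":
            return 0.5 * (1.0 - np.cos(w))
        return np.sin(w)


def preset(name: str) -> BreathingPreset:
    """Named breathing presets ('regular', 'active'); three cycles each."""
    try:
        amplitude, frequency = PRESET_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESET_TABLE)}"
        ) from None
    return BreathingPreset(amplitude=amplitude, frequency=frequency)


def vertical_profile(z, z_ov: float, z_top: float):
    """Linear decay weight: 1 at the diaphragm, 0 at and below the ovaries."""
    if z_top <= z_ov:
        raise ValueError("z_top must exceed z_ov")
    return np.clip((np.asarray(z, float) - z_ov) / (z_top - z_ov), 0.0, 1.0)


@dataclass
class DisplacementField:
    """Displacement values (m) at time ``time``.

    ``node_ids`` is None for a volumetric field defined on every mesh vertex;
    otherwise the field lives on exactly those (boundary) vertices.
    """

    values: np.ndarray
    time: float
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite values")

    def dense(self, n_nodes: int) -> np.ndarray:
        if self.node_ids is None:
            return self.values
        out = np.zeros((n_nodes, self.values.shape[1]))
        out[self.node_ids] = self.values
        return out


def boundary_displacement(mesh: Mesh, preset: BreathingPreset, z_ov: float,
                          t: float) -> DisplacementField:
    """Vertical (diaphragm-driven) part of the prescribed boundary motion.

    d_z(node) = direction * A * phi(z) * s(t); nodes at or below ``z_ov``
    do not move.  Defined on all boundary vertices.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    ids = mesh.boundary_node_ids()
    z = mesh.points[ids, -1]
    z_top = float(mesh.points[:, -1].max())
    phi = vertical_profile(z, z_ov, z_top)
    values = np.zeros((len(ids), mesh.dim))
    values[:, -1] = preset.direction * preset.amplitude * phi * preset.shape(t)
    return DisplacementField(values, t, ids)


def _compensation_directions(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Unit-magnitude horizontal dilation directions on boundary vertices.

    On the lateral walls this is the outward wall normal (magnitude 1); on
    the diaphragm it interpolates linearly across the cross-section, so the
    prescribed boundary field stays continuous at the wall/top corners.
    """
    ids = mesh.boundary_node_ids()
    pts = mesh.points[ids]
    d = np.zeros((len(ids), mesh.dim))
    for k in range(mesh.dim - 1):  # horizontal axes only
        lo, hi = mesh.points[:, k].min(), mesh.points[:, k].max()
        centre, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        d[:, k] = (pts[:, k] - centre) / half
    return ids, d


def volume_compensation(mesh: Mesh, vertical_field: DisplacementField,
                        z_ov: float, tol: float = 1e-4) -> DisplacementField:
    """Lateral displacement restoring the enclosed volume.

    A single magnitude ``g`` (times the vertical profile phi(z)) scales a
    horizontal dilation of the boundary: uniform outward/inward normal
    motion on the lateral walls, interpolated continuously across the
    diaphragm.  ``g`` is found by bracketed root-finding on
    the enclosed volume of the displaced boundary polygon/polyhedron, which
    is exact for straight facets, so the volume defect after compensation is
    limited only by the root-finder tolerance (default 1e-4 relative,
    comfortably below the 1e-3 isovolumetry requirement).
    """
    V0 = enclosed_volume(mesh.points, mesh.boundary_facets, mesh.dim)
    ids_lat, dirs = _compensation_directions(mesh)
    z_top = float(mesh.points[:, -1].max())
    phi = vertical_profile(mesh.points[ids_lat, -1], z_ov, z_top)
    dense_v = vertical_field.dense(mesh.n_nodes)

    def volume_at(g: float) -> float:
        disp = dense_v.copy()
        disp[ids_lat] += g * phi[:, None] * dirs
        return enclosed_volume(mesh.points + disp,
                               mesh.boundary_facets, mesh.dim)

    defect0 = volume_at(0.0) - V0
    if abs(defect0) <= tol * V0 * 1e-3:
        return DisplacementField(np.zeros_like(dirs), vertical_field.time,
                                 ids_lat)
    # first-order estimate: defect / effective lateral area, then bracket
    area_eff = _effective_lateral_area(mesh, z_ov)
    g0 = -defect0 / area_eff
    lo, hi = sorted((0.0, 2.0 * g0 if g0 != 0 else 1e-6))
    span = max(abs(g0), 1e-9)
    for _ in range(60):
        if (volume_at(lo) - V0) * (volume_at(hi) - V0) <= 0:
            break
        lo -= span
        hi += span
        span *= 2.0
    else:
        raise RuntimeError(
            "could not bracket the volume-compensation magnitude; residual "
            f"volume defect {defect0:.3e} m^3"
        )
    g = brentq(lambda s: volume_at(s) - V0, lo, hi,
               xtol=1e-14, rtol=8.9e-16)
    return DisplacementField(g * phi[:, None] * dirs, vertical_field.time,
                             ids_lat)


def _effective_lateral_area(mesh: Mesh, z_ov: float) -> float:
    from .geometry import _facet_areas

    idx = mesh.facets_of("lateral")
    facets = mesh.boundary_facets[idx]
    fa = _facet_areas(mesh.points, facets)
    z_top = float(mesh.points[:, -1].max())
    zc = mesh.points[facets][:, :, -1].mean(axis=1)
    phi = vertical_profile(zc, z_ov, z_top)
    return float((fa * phi).sum())


def prescribed_boundary_motion(mesh: Mesh, preset: BreathingPreset,
                               z_ov: float, t: float) -> DisplacementField:
    """Full prescribed boundary field: vertical forcing + volume compensation."""
    vert = boundary_displacement(mesh, preset, z_ov, t)
    comp = volume_compensation(mesh, vert, z_ov)
    dense = vert.dense(mesh.n_nodes) + comp.dense(mesh.n_nodes)
    ids = mesh.boundary_node_ids()
    return DisplacementField(dense[ids], t, ids)


# ---------------------------------------------------------------------------
# pseudo-solid mesh motion
# ---------------------------------------------------------------------------


@dataclass
class MeshMotionSettings:
    """Linear elastic mesh-motion parameters (only ratios matter).

    ``stiffening_exponent`` scales each element stiffness by
    (mean volume / element volume)**exponent, protecting small cells from
    inversion under large boundary excursions.
    """

    elastic_modulus: float = 1.0
    poisson_ratio: float = 0.3
    stiffening_exponent: float = 1.0
    linear_solver_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.linear_solver_tolerance <= 0:
            raise ValueError("linear_solver_tolerance must be positive")
        if self.stiffening_exponent < 0:
            raise ValueError("stiffening_exponent must be >= 0")


class MeshMotionSolver:
    """Factorized linear-elasticity solve on the reference mesh.

    Constant-strain P1 simplex elements; the displacement is always computed
    from the undeformed configuration, so the operator is assembled and
    factorized once and reused for every time level.
    """

    def __init__(self, mesh: Mesh, settings: MeshMotionSettings | None = None):
        self.mesh = mesh
        self.settings = settings or MeshMotionSettings()
        self.fixed_nodes = mesh.boundary_node_ids()
        K = _elastic_stiffness(mesh, self.settings)
        n = mesh.n_nodes
        d = mesh.dim
        fixed = np.concatenate([self.fixed_nodes + k * n for k in range(d)])
        self._n, self._d, self._fixed = n, d, fixed
        self._free = np.setdiff1d(np.arange(d * n), fixed)
        K = K.tocsc()
        self._Kfc = K[:, fixed][self._free]
        try:
            self._lu = splu(K[:, self._free][self._free])
        except RuntimeError as exc:  # pragma: no cover
            raise RuntimeError(f"singular mesh-motion system: {exc}") from exc

    def solve(self, boundary_disp: DisplacementField) -> DisplacementField:
        n, d = self._n, self._d
        # boundary nodes absent from the field are held fixed (zero)
        dense = boundary_disp.dense(n)
        vals = np.concatenate([dense[self.fixed_nodes, k] for k in range(d)])
        x = np.zeros(d * n)
        x[self._fixed] = vals
        x[self._free] = self._lu.solve(-self._Kfc @ vals)
        disp = np.stack([x[k * n:(k + 1) * n] for k in range(d)], axis=1)
        new_pts = self.mesh.points + disp
        from .geometry import _signed_simplex_volumes
        vols = _signed_simplex_volumes(new_pts, self.mesh.cells)
        if np.any(vols <= 0):
            bad = np.nonzero(vols <= 0)[0][:10].tolist()
            raise RuntimeError(
                f"mesh motion inverted elements {bad}; increase "
                "stiffening_exponent or reduce the forcing amplitude"
            )
        return DisplacementField(disp, boundary_disp.time, None)


def solve_mesh_motion(mesh: Mesh, boundary_disp: DisplacementField,
                      settings: MeshMotionSettings | None = None
                      ) -> DisplacementField:
    """One-off pseudo-solid propagation of a boundary displacement field."""
    return MeshMotionSolver(mesh, settings).solve(boundary_disp)


def _elastic_stiffness(mesh: Mesh, settings: MeshMotionSettings
                       ) -> sp.coo_matrix:
    """Vector P1 stiffness, blocked [all x; all y(; all z)] like the flow dofs."""
    E, nu = settings.elastic_modulus, settings.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    muL = E / (2 * (1 + nu))
    pts, cells, d = mesh.points, mesh.cells, mesh.dim
    tri = pts[cells]
    ne, nloc = cells.shape[0], cells.shape[1]
    J = np.stack([tri[:, k + 1] - tri[:, 0] for k in range(d)], axis=2)
    detJ = np.linalg.det(J)
    vols = detJ / (2.0 if d == 2 else 6.0)
    invJ = np.linalg.inv(J)
    gref = np.vstack([-np.ones((1, d)), np.eye(d)])  # (nloc, d)
    G = np.einsum("ak,ekd->ead", gref, invJ)  # physical gradients
    scale = vols.copy()
    if settings.stiffening_exponent > 0:
        scale = vols * (vols.mean() / vols) ** settings.stiffening_exponent
    n = mesh.n_nodes
    rows, cols, data = [], [], []
    for i in range(d):       # test component
        for j in range(d):   # trial component
            # mu (grad u + grad u^T) : grad v  +  lam div u div v
            k_ij = muL * np.einsum("e,ead,ebd->eab", scale,
                                   G, G) * (1.0 if i == j else 0.0)
            k_ij = k_ij + muL * np.einsum("e,ea,eb->eab", scale,
                                          G[:, :, j], G[:, :, i])
            k_ij = k_ij + lam * np.einsum("e,ea,eb->eab", scale,
                                          G[:, :, i], G[:, :, j])
            rows.append((np.repeat(cells, nloc, axis=1) + i * n).ravel())
            cols.append((np.tile(cells, (1, nloc)) + j * n).ravel())
            data.append(k_ij.ravel())
    return sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(d * n, d * n),
    )


def mesh_velocity(disp_history: list[DisplacementField], dt: float,
                  scheme: str = "backward_difference_1") -> np.ndarray:
    """Mesh velocity (m/s) at the newest time level by backward differences.

    The finite-difference order matches the flow time integrator so the
    discrete wall velocity is consistent with the wall displacement.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if scheme == "backward_difference_1":
        if len(disp_history) < 2:
            raise ValueError("BDF1 mesh velocity needs 2 displacement levels")
        return (disp_history[-1].values - disp_history[-2].values) / dt
    if scheme == "backward_difference_2":
        if len(disp_history) < 3:
            raise ValueError("BDF2 mesh velocity needs 3 displacement levels")
        return (3 * disp_history[-1].values - 4 * disp_history[-2].values
                + disp_history[-3].values) / (2 * dt)
    raise ValueError(f"unknown scheme {scheme!r}")
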