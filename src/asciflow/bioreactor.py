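"""Perfusion-bioreactor shear model and inverse operating-point design.

Two decoupled stages mirror the device physics: (1) pump-driven flow through
the cell-laden porous hydrogel plug in each radial chamber, modelled with
the Brinkman equation (mu_eff lap(u) - (mu/k) u = grad p, div u = 0,
mu_eff = mu / porosity) and averaged to a single superficial speed; (2) an
idealized cell — a semicircular bump (2D default) on the floor of an open
flow channel — exposed to that speed, from which the FSS profile over the
cell's arclength is computed.  Inverting stage (2) for a target peak FSS
(1, 5 or 11 dynes/cm^2: interstitial, average-ascitic and elevated-ascitic
shear) yields the channel inlet speed and pump rate; in the Stokes regime a
single forward solve fixes the FSS-per-unit-speed slope, so the inversion
is one division plus a verification solve.

The device's chamber and cell dimensions are not part of the public record;
the defaults here are documented placeholders and should be overridden with
measured values for quantitative use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._fem import Assembler, saddle_system, solve_with_dirichlet
from .flow import FluidProperties
from .geometry import Mesh, build_channel_mesh, graded_points
from .wss import PA_TO_DYN_CM2, wall_shear

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HydrogelSpec:
    """Porous-plug properties of the agarose/collagen IPN hydrogel.

    ``permeability`` and ``porosity`` are placeholders representative of a
    3% (w/v) agarose gel; both should come from rheometry/porosimetry of
    the actual material.
    """

    permeability: float = 1e-14   # m^2
    porosity: float = 0.85
    plug_length: float = 0.010    # m

    def __post_init__(self) -> None:
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if self.plug_length <= 0:
            raise ValueError("plug_length must be positive")


@dataclass(frozen=True)
class ChamberSpec:
    """Radial-chamber layout; the pump rate is shared by ``n_chambers``."""

    n_chambers: int = 8
    width: float = 0.004     # m, chamber cross-section width
    height: float = 0.004    # m, chamber cross-section height
    pump_rate: float = 0.0   # m^3/s total

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise ValueError("n_chambers must be >= 1")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.pump_rate < 0:
            raise ValueError("pump_rate must be non-negative")

    @property
    def cross_section_area(self) -> float:
        return self.width * self.height

    def superficial_speed(self) -> float:
        """Flow rate per chamber divided by plug cross-section (m/s)."""
        return self.pump_rate / (self.n_chambers * self.cross_section_area)


@dataclass(frozen=True)
class CellModel:
    """Idealized adherent cell in an open flow channel.

    The cell is a hemispherical (3D) or semicircular (2D, default) bump of
    radius ``cell_radius`` on the channel floor; ``inlet_speed`` is the
    mean speed of the fully developed inflow.
    """

    cell_radius: float = 7.5e-6   # m
    channel_height: float = 100e-6  # m
    channel_length: float | None = None  # default 6 x height
    shape: str = "semicircular_bump"
    inlet_speed: float = 0.0
    resolution: int = 16          # velocity intervals across the bump arc

    def __post_init__(self) -> None:
        if self.cell_radius <= 0 or self.channel_height <= 0:
            raise ValueError("cell_radius and channel_height must be positive")
        if self.cell_radius >= self.channel_height / 2:
            raise ValueError(
                "cell too large for the channel: require "
                "cell_radius < channel_height / 2")
        if self.shape not in ("semicircular_bump", "hemisphere_on_wall"):
            raise ValueError(f"unknown cell shape {self.shape!r}")
        if self.inlet_speed < 0:
            raise ValueError("inlet_speed must be non-negative")

    @property
    def length(self) -> float:
        return (self.channel_length if self.channel_length is not None
                else 6.0 * self.channel_height)


@dataclass
class OperatingPoint:
    """Bioreactor setting realizing a target peak cell-surface FSS."""

    target_fss: float       # dynes/cm^2
    inlet_speed: float      # m/s
    pump_rate: float        # m^3/s
    achieved_fss: float     # dynes/cm^2
    residual: float         # |achieved - target| / target

    def to_dict(self) -> dict:
        return {
            "target_fss_dyn_cm2": self.target_fss,
            "inlet_speed_m_s": self.inlet_speed,
            "pump_rate_m3_s": self.pump_rate,
            "achieved_fss_dyn_cm2": self.achieved_fss,
            "residual": self.residual,
        }


# ---------------------------------------------------------------------------
# stage 1: porous plug
# ---------------------------------------------------------------------------


def chamber_flow(chamber: ChamberSpec, gel: HydrogelSpec,
                 props: FluidProperties | None = None,
                 method: str = "brinkman",
                 resolution: int = 24) -> tuple[dict, float]:
    """Flow through one hydrogel plug; returns (field dict, averaged speed).

    ``method='brinkman'`` solves the 2D Brinkman problem on the plug
    cross-section (length x height) with no-slip lateral walls and the
    superficial speed imposed at inlet and outlet; ``method='darcy'`` is the
    closed-form plug-flow fast path (uniform superficial speed), appropriate
    when the Brinkman screening length sqrt(k/porosity) is far below the
    mesh scale.
    """
    props = props or FluidProperties()
    U_s = chamber.superficial_speed()
    if method == "darcy" or U_s == 0.0:
        return ({"method": "darcy", "superficial_speed": U_s}, U_s)
    if method != "brinkman":
        raise ValueError("method must be 'brinkman' or 'darcy'")
    mu = props.dynamic_viscosity
    mu_eff = mu / gel.porosity
    drag = mu / gel.permeability
    L, h = gel.plug_length, chamber.height
    nx = max(8, int(round(resolution * L / h)))
    mesh = build_channel_mesh(L, h, nx, resolution)
    asm = Assembler(mesh, velocity_degree=2)
    A = asm.viscous(mu_eff) + asm.mass(drag)
    B = asm.divergence()
    S = saddle_system(A, B)
    nV = asm.V.ndof
    vc = asm.vcoords
    walls = np.concatenate([asm.V.boundary_dofs("floor"),
                            asm.V.boundary_dofs("top")])
    io = np.concatenate([asm.V.boundary_dofs("inlet"),
                         asm.V.boundary_dofs("outlet")])
    io = np.setdiff1d(io, walls)
    # scale the near-uniform inflow so the *discrete* flux equals Q per
    # chamber (the pump is flow-rate controlled)
    prof = np.zeros(asm.V.ndof)
    prof[io] = U_s
    flux = _facet_flux(asm, "inlet", prof)
    prof[io] *= U_s * h / flux
    fixed = np.concatenate([walls, nV + walls, io, nV + io,
                            [2 * nV]])  # + pinned pressure
    vals = np.concatenate([np.zeros(2 * len(walls)),
                           prof[io], np.zeros(len(io)), [0.0]])
    x = solve_with_dirichlet(S.tocsr(), np.zeros(S.shape[0]), fixed, vals)
    u = x[:2 * nV]
    cd = asm.V.cell_dofs
    ux = np.einsum("qa,ea->eq", asm._bv, u[:nV][cd])
    # volume-averaged axial speed = superficial speed by mass conservation
    U_gel = float((asm.w * ux).sum() / asm.w.sum())
    field = {
        "method": "brinkman",
        "mesh": mesh,
        "velocity": np.stack([u[:nV], u[nV:]], axis=1),
        "superficial_speed": U_s,
    }
    return field, U_gel


def _facet_flux(asm: Assembler, patch: str, scalar_nodal: np.ndarray) -> float:
    """Integral of a nodal scalar over a patch's facets (3-pt Gauss)."""
    from ._fem import _GAUSS3_W, _GAUSS3_X
    mesh = asm.mesh
    idx = mesh.facets_of(patch)
    fd = asm.V.facet_dofs[idx]
    p = asm.coords[mesh.boundary_facets[idx]]
    L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    s = _GAUSS3_X
    if asm.V.degree == 2:
        basis = np.stack([(1 - s) * (1 - 2 * s), s * (2 * s - 1),
                          4 * s * (1 - s)], axis=1)
    else:
        basis = np.stack([1 - s, s], axis=1)
    vq = np.einsum("fa,qa->fq", scalar_nodal[fd], basis)
    return float((vq * _GAUSS3_W[None, :]).sum(axis=1) @ L)


# ---------------------------------------------------------------------------
# stage 2: idealized cell in an open channel
# ---------------------------------------------------------------------------


def _cell_channel_mesh(cell: CellModel) -> Mesh:
    a, h, L = cell.cell_radius, cell.channel_height, cell.length
    xc = L / 2

    def profile(x: np.ndarray) -> np.ndarray:
        d2 = a * a - (np.atleast_1d(x) - xc) ** 2
        return np.where(d2 > 0, np.sqrt(np.maximum(d2, 0.0)), 0.0)

    # x grid: fine band across the bump, coarser graded flanks
    n_b = cell.resolution
    fine = np.linspace(xc - 2 * a, xc + 2 * a, 2 * n_b + 1)
    n_side = max(6, n_b // 2)
    left = graded_points(0.0, xc - 2 * a, n_side, cluster=1.8, side="end")
    right = graded_points(xc + 2 * a, L, n_side, cluster=1.8, side="start")
    x = np.unique(np.concatenate([left, fine, right]))
    ny = max(12, n_b)
    return build_channel_mesh(L, h, len(x) - 1, ny, floor_profile=profile,
                              bump_patch="cell", x_grid=x, y_cluster=1.2)


def cell_fss_profile(cell: CellModel, props: FluidProperties | None = None
                     ) -> dict:
    """Steady FSS along the idealized cell's surface arclength.

    Solves Stokes flow (the cell-scale Reynolds number is far below unity
    at bioreactor speeds; a warning is logged otherwise) in the bump channel
    with fully developed Poiseuille inflow/outflow of mean ``inlet_speed``
    and no-slip on every wall.  Returns arclength (m, from the upstream
    base), FSS (dynes/cm^2), peak and surface-mean values, and the flat-wall
    reference 6 mu U / h.
    """
    props = props or FluidProperties()
    mu = props.dynamic_viscosity
    U = cell.inlet_speed
    h = cell.channel_height
    re_cell = props.density * U * 2 * cell.cell_radius / mu
    if re_cell > 0.1:
        log.warning("cell Reynolds number %.3g exceeds 0.1; the Stokes "
                    "model underestimates convective asymmetry", re_cell)
    mesh = _cell_channel_mesh(cell)
    asm = Assembler(mesh, velocity_degree=2)
    nV = asm.V.ndof
    arc, ids = _cell_arclength(asm, cell)
    if U == 0.0:
        zero = np.zeros_like(arc)
        return {"arclength_m": arc, "fss_dyn_cm2": zero, "peak_fss": 0.0,
                "mean_fss": 0.0, "flat_wall_fss": 0.0, "mesh": mesh,
                "peak_arclength_m": 0.0}
    A = asm.viscous(mu)
    B = asm.divergence()
    S = saddle_system(A, B)
    vc = asm.vcoords
    bdofs = asm.V.boundary_dofs()
    io = np.concatenate([asm.V.boundary_dofs("inlet"),
                         asm.V.boundary_dofs("outlet")])
    ux = np.zeros(asm.V.ndof)
    ux[io] = 6 * U * vc[io, 1] * (h - vc[io, 1]) / h ** 2
    fixed = np.concatenate([bdofs, nV + bdofs, [2 * nV]])
    vals = np.concatenate([ux[bdofs], np.zeros(len(bdofs)), [0.0]])
    x = solve_with_dirichlet(S.tocsr(), np.zeros(S.shape[0]), fixed, vals)
    u, p = x[:2 * nV], x[2 * nV:2 * nV + asm.Q.ndof]
    r = A @ u + B.T @ p
    m = asm.facet_lumped_mass()
    nids, normals = asm.nodal_normals()
    pos = np.searchsorted(nids, ids)
    traction = np.stack([r[ids] / m[ids], r[nV + ids] / m[ids]], axis=1)
    tau = wall_shear(traction, normals[pos])
    fss = PA_TO_DYN_CM2 * np.linalg.norm(tau, axis=1)
    kmax = int(np.argmax(fss))
    floor_ids = asm.V.boundary_dofs("floor")
    fpos = np.searchsorted(nids, floor_ids)
    ftr = np.stack([r[floor_ids] / m[floor_ids],
                    r[nV + floor_ids] / m[floor_ids]], axis=1)
    ffss = PA_TO_DYN_CM2 * np.linalg.norm(
        wall_shear(ftr, normals[fpos]), axis=1)
    return {
        "arclength_m": arc,
        "fss_dyn_cm2": fss,
        "peak_fss": float(fss[kmax]),
        "peak_arclength_m": float(arc[kmax]),
        "mean_fss": float(np.trapezoid(fss, arc) / (arc[-1] - arc[0])),
        "flat_wall_fss": PA_TO_DYN_CM2 * 6 * mu * U / h,
        "floor_x_m": asm.vcoords[floor_ids, 0],
        "floor_fss_dyn_cm2": ffss,
        "mesh": mesh,
    }


def _cell_arclength(asm: Assembler, cell: CellModel
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Arclength coordinate (upstream base -> downstream base) of cell nodes."""
    ids = asm.V.boundary_dofs("cell")
    a = cell.cell_radius
    xc = cell.length / 2
    vc = asm.vcoords[ids]
    ang = np.arctan2(vc[:, 1], vc[:, 0] - xc)  # pi at upstream base, 0 down
    arc = a * (np.pi - ang)
    order = np.argsort(arc)
    return arc[order], ids[order]


def peak_cell_fss(profile: dict) -> tuple[float, float]:
    """(peak FSS in dynes/cm^2, arclength location in m) of a profile."""
    fss = np.asarray(profile["fss_dyn_cm2"])
    if fss.size == 0:
        raise ValueError("empty FSS profile")
    k = int(np.argmax(fss))
    return float(fss[k]), float(np.asarray(profile["arclength_m"])[k])


# ---------------------------------------------------------------------------
# inverse design
# ---------------------------------------------------------------------------


def inverse_design(target_fss: float, cell: CellModel,
                   chamber: ChamberSpec, gel: HydrogelSpec,
                   props: FluidProperties | None = None,
                   reference_speed: float = 1e-3) -> OperatingPoint:
    """Operating point whose peak cell FSS matches ``target_fss`` within 1%.

    Stokes linearity makes peak FSS proportional to the inlet speed, so one
    forward solve at ``reference_speed`` fixes the slope; a verification
    solve at the returned speed confirms the residual.  The pump rate maps
    the inlet speed back through the plug superficial-speed relation.
    """
    if target_fss <= 0:
        raise ValueError("target_fss must be positive")
    props = props or FluidProperties()
    ref = cell.__class__(**{**cell.__dict__, "inlet_speed": reference_speed})
    fwd = cell_fss_profile(ref, props)
    slope = fwd["peak_fss"] / reference_speed
    if slope <= 0:
        raise RuntimeError("forward model produced zero shear; the target "
                           "is unreachable with this geometry")
    U = target_fss / slope
    chk = cell.__class__(**{**cell.__dict__, "inlet_speed": U})
    achieved = cell_fss_profile(chk, props)["peak_fss"]
    residual = abs(achieved - target_fss) / target_fss
    if residual > 0.01:
        raise RuntimeError(
            f"inverse design residual {residual:.3%} exceeds 1%; attainable "
            f"range is linear in speed with slope {slope:.3g} "
            "(dyn/cm^2)/(m/s)")
    Q = U * chamber.n_chambers * chamber.cross_section_area
    return OperatingPoint(
        target_fss=target_fss,
        inlet_speed=U,
        pump_rate=Q,
        achieved_fss=achieved,
        residual=residual,
    )
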