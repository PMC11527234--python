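"""Wall shear stress extraction and cycle metrics.

The wall traction t = sigma . n (sigma = -p I + mu (grad u + grad u^T),
n outward from the fluid) is recovered variationally: the flow solver saves
the boundary momentum residual — the integral of sigma . n against each
boundary test function — and dividing by the lumped boundary mass turns it
into nodal traction vectors.  This "consistent flux" recovery is markedly
more accurate on simplex meshes than differentiating the velocity at the
wall.  The fluid shear stress (FSS) is the tangential projection
tau_w = t - (t.n) n, reported both in Pa and dynes/cm^2 (1 Pa = 10 dyn/cm^2).

Reported cycle metrics are the standard read-outs for breathing-driven
ascitic flow:
per-ovary mean FSS (area-weighted spatial mean, then time-averaged over the
final forcing cycle), per-ovary peak FSS (maximum over boundary nodes and
snapshot times of the final cycle), and domain mean/peak speed
(volume-weighted |u|, time-averaged / maximized over the final cycle),
printed in cm/s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._fem import Assembler
from .flow import FlowHistory, FlowState, FluidProperties, _flat
from .geometry import Mesh

PA_TO_DYN_CM2 = 10.0
M_S_TO_CM_S = 100.0


@dataclass
class WSSField:
    """Tangential wall traction at boundary velocity nodes of one patch."""

    node_ids: np.ndarray
    tau: np.ndarray        # (n, dim) Pa, tangential
    normals: np.ndarray    # (n, dim) outward unit normals
    time: float
    patch: str

    @property
    def magnitude_pa(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=1)

    @property
    def magnitude_dyn_cm2(self) -> np.ndarray:
        return PA_TO_DYN_CM2 * self.magnitude_pa


@dataclass
class PatchMetrics:
    """Final-cycle FSS statistics on one wall patch (dynes/cm^2)."""

    patch: str
    mean_fss: float
    peak_fss: float
    times: np.ndarray = field(repr=False)
    spatial_max_series: np.ndarray = field(repr=False)
    spatial_mean_series: np.ndarray = field(repr=False)


@dataclass
class CycleSummary:
    """Headline metrics of the final forcing cycle of a cavity run."""

    mean_speed_cm_s: float
    peak_speed_cm_s: float
    patches: dict[str, PatchMetrics]
    preset_name: str | None
    config_digest: str

    def to_dict(self) -> dict:
        return {
            "mean_speed_cm_s": self.mean_speed_cm_s,
            "peak_speed_cm_s": self.peak_speed_cm_s,
            "config_digest": self.config_digest,
            "preset": self.preset_name,
            "patches": {
                name: {
                    "mean_fss_dyn_cm2": pm.mean_fss,
                    "peak_fss_dyn_cm2": pm.peak_fss,
                    "times_s": pm.times.tolist(),
                    "spatial_max_dyn_cm2": pm.spatial_max_series.tolist(),
                    "spatial_mean_dyn_cm2": pm.spatial_mean_series.tolist(),
                }
                for name, pm in self.patches.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


# ---------------------------------------------------------------------------
# traction / shear extraction
# ---------------------------------------------------------------------------


def wall_traction(state: FlowState, mesh: Mesh, patch: str,
                  props: FluidProperties,
                  velocity_degree: int = 2,
                  asm: Assembler | None = None) -> tuple[np.ndarray,
                                                         np.ndarray,
                                                         np.ndarray]:
    """Nodal traction vectors (Pa) on ``patch``: (node_ids, traction, normals).

    Uses the solver-saved boundary momentum residual when available
    (consistent with the full discrete momentum balance, including inertia
    and convection); otherwise assembles the steady Stokes residual
    A u + B^T p on the state's configuration, which is exact for the
    hydrostatic and steady fixture states used in verification.
    Zero-measure nodes (e.g. on an axisymmetric axis) are dropped.
    An existing ``asm`` (already set to the state's configuration) may be
    passed to amortize setup across snapshots.
    """
    if asm is None:
        asm = Assembler(mesh, velocity_degree=velocity_degree)
        asm.set_coords(mesh.points + state.mesh_displacement)
    nV = asm.V.ndof
    if state.wall_reactions is not None:
        r = state.wall_reactions
        m = (state.boundary_mass if state.boundary_mass is not None
             else asm.facet_lumped_mass())
    else:
        A = asm.viscous(props.dynamic_viscosity)
        B = asm.divergence()
        u = _flat(state.velocity)
        rflat = A @ u + B.T @ state.pressure
        r = np.stack([rflat[:nV], rflat[nV:]], axis=1)
        m = asm.facet_lumped_mass()
    pdofs = asm.V.boundary_dofs(patch)
    ok = m[pdofs] > 1e-12 * m.max()
    pdofs = pdofs[ok]
    if pdofs.size == 0:
        raise ValueError(f"patch {patch!r} has no boundary nodes with measure")
    ids, normals = asm.nodal_normals()
    pos = np.searchsorted(ids, pdofs)
    traction = r[pdofs] / m[pdofs, None]
    return pdofs, traction, normals[pos]


def wall_shear(traction: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Tangential projection tau_w = t - (t.n) n; requires unit normals."""
    norm = np.linalg.norm(normals, axis=1)
    if not np.allclose(norm, 1.0, atol=1e-8):
        raise ValueError("normals must be unit vectors")
    tn = np.einsum("ij,ij->i", traction, normals)
    return traction - tn[:, None] * normals


def wss_field(state: FlowState, mesh: Mesh, patch: str,
              props: FluidProperties, velocity_degree: int = 2,
              asm: Assembler | None = None) -> WSSField:
    """Convenience: traction extraction + tangential projection on a patch."""
    ids, traction, normals = wall_traction(state, mesh, patch, props,
                                           velocity_degree, asm=asm)
    tau = wall_shear(traction, normals)
    return WSSField(ids, tau, normals, state.time, patch)


# ---------------------------------------------------------------------------
# cycle metrics
# ---------------------------------------------------------------------------


def _patch_node_weights(asm: Assembler, patch: str,
                        pdofs: np.ndarray) -> np.ndarray:
    """Area weights restricted to one patch's facets (for spatial means)."""
    mesh = asm.mesh
    idx = mesh.facets_of(patch)
    fd = asm.V.facet_dofs[idx]
    p = asm.coords[mesh.boundary_facets[idx]]
    L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    if asm.V.degree == 2:
        per = np.stack([L / 6, L / 6, 2 * L / 3], axis=1)
    else:
        per = np.stack([L / 2, L / 2], axis=1)
    w = np.zeros(asm.V.ndof)
    np.add.at(w, fd, per)
    return w[pdofs]


def patch_metrics(wss_history: list[WSSField], mesh: Mesh,
                  patch: str, velocity_degree: int = 2) -> PatchMetrics:
    """Final-cycle FSS statistics from a sequence of per-snapshot WSS fields.

    mean = area-weighted spatial mean at each snapshot, then averaged over
    the snapshots; peak = maximum over nodes and snapshots.
    """
    fields = [f for f in wss_history if f.patch == patch]
    if not fields:
        raise ValueError(f"no WSS fields for patch {patch!r}")
    asm = Assembler(mesh, velocity_degree=velocity_degree)
    w = _patch_node_weights(asm, patch, fields[0].node_ids)
    if w.sum() <= 0:
        raise ValueError(f"patch {patch!r} has zero area")
    means, maxes, times = [], [], []
    for f in fields:
        mag = f.magnitude_dyn_cm2
        means.append(float((w * mag).sum() / w.sum()))
        maxes.append(float(mag.max()))
        times.append(f.time)
    return PatchMetrics(
        patch=patch,
        mean_fss=float(np.mean(means)),
        peak_fss=float(np.max(maxes)),
        times=np.array(times),
        spatial_max_series=np.array(maxes),
        spatial_mean_series=np.array(means),
    )


def velocity_metrics(history: FlowHistory, mesh: Mesh,
                     final_cycle_only: bool = True,
                     _asm: Assembler | None = None) -> tuple[float, float]:
    """(mean_speed, peak_speed) in cm/s over the final recorded cycle.

    mean = volume-weighted average of |u| (quadrature on the displaced
    configuration), then time-averaged with uniform snapshot weights;
    peak = max of |u| over velocity nodes and snapshots.
    """
    states = history.final_cycle() if final_cycle_only else history.states
    if not states:
        raise ValueError("history holds no snapshots")
    deg = history.settings.velocity_degree if history.settings else 2
    asm = _asm or Assembler(mesh, velocity_degree=deg)
    means, peaks = [], []
    for s in states:
        asm.set_coords(mesh.points + s.mesh_displacement)
        u = _flat(s.velocity)
        cd = asm.V.cell_dofs
        ux = np.einsum("qa,ea->eq", asm._bv, u[:asm.V.ndof][cd])
        uy = np.einsum("qa,ea->eq", asm._bv, u[asm.V.ndof:][cd])
        speed = np.hypot(ux, uy)
        vol = asm.w.sum()
        means.append(float((asm.w * speed).sum() / vol))
        peaks.append(float(s.speed().max()))
    return (M_S_TO_CM_S * float(np.mean(means)),
            M_S_TO_CM_S * float(np.max(peaks)))


def summarize(history: FlowHistory, mesh: Mesh,
              patches: tuple[str, ...] = ("ovary_left", "ovary_right"),
              config: dict | None = None) -> CycleSummary:
    """Aggregate final-cycle velocity and per-ovary FSS metrics."""
    props = history.props or FluidProperties()
    deg = history.settings.velocity_degree if history.settings else 2
    asm = Assembler(mesh, velocity_degree=deg)
    mean_speed, peak_speed = velocity_metrics(history, mesh, _asm=asm)
    fields: dict[str, list[WSSField]] = {p: [] for p in patches}
    for s in history.final_cycle():
        asm.set_coords(mesh.points + s.mesh_displacement)
        for patch in patches:
            fields[patch].append(wss_field(s, mesh, patch, props, deg,
                                           asm=asm))
    pm = {patch: patch_metrics(fields[patch], mesh, patch, deg)
          for patch in patches}
    digest_src = config if config is not None else {
        "preset": None if history.preset is None
        else asdict(history.preset),
        "n_nodes": mesh.n_nodes,
        "n_cells": mesh.n_cells,
    }
    return CycleSummary(
        mean_speed_cm_s=mean_speed,
        peak_speed_cm_s=peak_speed,
        patches=pm,
        preset_name=None,
        config_digest=config_digest(digest_src),
    )


def config_digest(config: dict) -> str:
    """Stable hash of a configuration mapping (order-insensitive)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
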