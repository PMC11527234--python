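"""Incompressible ALE Navier-Stokes on the moving cavity mesh.

Momentum and mass balance in arbitrary Lagrangian-Eulerian form,

    rho (du/dt|mesh + ((u - w) . grad) u) = div(-p I + mu (grad u + grad u^T))
    div u = 0,

with the mesh velocity ``w`` entering the convective term, no-slip ``u = w``
on every wall, and the fluid starting from rest.  Discretization: Taylor-Hood
P2/P1 (default) or stabilized equal-order P1/P1 triangles, implicit backward
differences in time, Picard linearization of convection in skew-symmetric
form, direct sparse LU.  Enclosed-flow pressure is fixed by a zero-mean
Lagrange multiplier (default) or by pinning one node.

Node-following ALE: fields are attached to mesh nodes, so the discrete time
derivative at a node is exactly the ALE derivative; mass, viscous and
convective operators are assembled on the configuration at the new time
level with w from the same backward difference as the time scheme (uniform
mesh translation then preserves a uniform flow to solver precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin
from ._fem import Assembler, DirichletSolver, saddle_system
from .geometry import CavitySpec, Mesh, compute_volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian ascites-like fluid; defaults are slightly hyperdense saline."""

    density: float = 1017.5       # kg/m^3
    dynamic_viscosity: float = 0.0012  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass
class SolverSettings:
    """Discretization controls for the transient flow solve.

    ``dt = None`` resolves the forcing period with ``steps_per_cycle``
    steps.  ``convection = False`` drops the convective term (Stokes test
    mode).  ``pressure_constraint`` is "zero_mean" or "pin_node".
    """

    dt: float | None = None
    steps_per_cycle: int = 200
    n_cycles: int = 3
    element_pair: str = "taylor_hood"
    time_scheme: str = "backward_difference_1"
    linearization: str = "picard"
    nonlinear_tolerance: float = 1e-4
    linear_tolerance: float = 1e-12
    max_nonlinear_iterations: int = 2
    pressure_constraint: str = "zero_mean"
    convection: bool = True
    upwind: float = 1.0
    snapshot_stride: int = 5

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.nonlinear_tolerance <= 0 or self.linear_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.element_pair not in ("taylor_hood", "equal_order_stabilized"):
            raise ValueError(f"unknown element_pair {self.element_pair!r}")
        if self.time_scheme not in ("backward_difference_1",
                                    "backward_difference_2"):
            raise ValueError(f"unknown time_scheme {self.time_scheme!r}")
        if self.pressure_constraint not in ("zero_mean", "pin_node"):
            raise ValueError(
                f"unknown pressure_constraint {self.pressure_constraint!r}")
        if self.linearization != "picard":
            raise ValueError("only Picard linearization of the convective "
                             "term is implemented")

    @property
    def velocity_degree(self) -> int:
        return 2 if self.element_pair == "taylor_hood" else 1

    @classmethod
    def desk(cls) -> "SolverSettings":
        """Desk-scale cavity-run settings: 100 implicit steps per forcing
        cycle with lagged (one-sweep) convection; resolves the breathing
        cycle while keeping a three-cycle run around a hundred seconds on
        one core."""
        return cls(steps_per_cycle=100, snapshot_stride=5,
                   max_nonlinear_iterations=1)


@dataclass
class FlowState:
    """Velocity/pressure plus mesh displacement and velocity at one time.

    ``wall_reactions`` holds the discrete boundary momentum residual
    (integral of sigma.n against boundary test functions) saved by the
    solver; the wss module turns it into nodal tractions.
    """

    velocity: np.ndarray          # (ndof_v, dim) m/s
    pressure: np.ndarray          # (ndof_p,) Pa
    mesh_displacement: np.ndarray  # (n_vertices, dim) m
    mesh_velocity: np.ndarray     # (ndof_v, dim) m/s
    time: float
    wall_reactions: np.ndarray | None = None   # (ndof_v, dim)
    boundary_mass: np.ndarray | None = None    # (ndof_v,)

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


@dataclass
class FlowHistory:
    """Snapshots at a fixed stride plus run metadata."""

    mesh: Mesh
    states: list[FlowState] = field(default_factory=list)
    preset: kin.BreathingPreset | None = None
    settings: SolverSettings | None = None
    props: FluidProperties | None = None
    snapshots_per_cycle: int | None = None
    periodicity_residuals: list[float] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def n_cycles_recorded(self) -> int:
        if not self.snapshots_per_cycle:
            return 0
        return len(self.states) // self.snapshots_per_cycle

    def cycle_states(self, cycle: int) -> list[FlowState]:
        """States of 1-based forcing cycle ``cycle``."""
        k = self.snapshots_per_cycle
        if not k:
            raise ValueError("history has no cycle bookkeeping")
        out = self.states[(cycle - 1) * k: cycle * k]
        if len(out) != k:
            raise ValueError(f"cycle {cycle} not fully recorded")
        return out

    def final_cycle(self) -> list[FlowState]:
        return self.cycle_states(self.n_cycles_recorded())


class FlowSolver:
    """ALE Navier-Stokes stepper bound to one mesh topology."""

    def __init__(self, mesh: Mesh, props: FluidProperties,
                 settings: SolverSettings):
        self.mesh = mesh
        self.props = props
        self.settings = settings
        self.asm = Assembler(mesh, velocity_degree=settings.velocity_degree)
        nV = self.asm.V.ndof
        self.nV = nV
        self.nQ = self.asm.Q.ndof
        bdofs = self.asm.V.boundary_dofs()
        self._bdofs = bdofs
        # the linear solve always pins one pressure dof (keeps the matrix
        # fully sparse); the zero-mean constraint is applied as a post-shift
        fixed = np.concatenate([bdofs, nV + bdofs, [2 * nV]])
        self._ntot = 2 * nV + self.nQ
        self._solver = DirichletSolver(self._ntot, fixed)
        self._zero_mean = settings.pressure_constraint == "zero_mean"

    def initial_state(self) -> FlowState:
        nV, d = self.nV, 2
        return FlowState(
            velocity=np.zeros((nV, d)),
            pressure=np.zeros(self.nQ),
            mesh_displacement=np.zeros((self.mesh.n_nodes, d)),
            mesh_velocity=np.zeros((nV, d)),
            time=0.0,
        )

    # -- single implicit step ----------------------------------------------

    def advance(self, state: FlowState, coords_new: np.ndarray,
                w_new: np.ndarray, dt: float,
                state_prev: FlowState | None = None,
                body_force=None,
                bc_values: np.ndarray | None = None) -> FlowState:
        """Advance one step to the configuration ``coords_new``.

        ``w_new``: mesh velocity at velocity nodes, (ndof_v, dim).
        BDF2 is used when ``state_prev`` is given and the settings ask for
        it; the first step of a run falls back to BDF1.  ``bc_values``
        overrides the default no-slip wall data u = w (blocked layout
        [x on boundary dofs; y on boundary dofs]), for verification flows
        driven through open ends.
        """
        st = self.settings
        asm = self.asm
        asm.set_coords(coords_new)
        mu = self.props.dynamic_viscosity
        rho = self.props.density

        A = asm.viscous(mu)
        B = asm.divergence()
        M = asm.mass(rho)
        stab = None
        if st.element_pair == "equal_order_stabilized":
            stab = (0.05 / mu) * asm.pressure_laplacian()

        use_bdf2 = (st.time_scheme == "backward_difference_2"
                    and state_prev is not None)
        if use_bdf2:
            c0, hist = 1.5, 2.0 * _flat(state.velocity) - 0.5 * _flat(
                state_prev.velocity)
        else:
            c0, hist = 1.0, _flat(state.velocity)

        F = asm.load(body_force) if body_force is not None else np.zeros(
            2 * self.nV)
        F_hist = (M / dt) @ hist

        if bc_values is None:
            u_bc = _flat(w_new)[np.concatenate([self._bdofs,
                                                self.nV + self._bdofs])]
        else:
            u_bc = np.asarray(bc_values, float)
        vals = np.concatenate([u_bc, [0.0]])  # pinned pressure dof

        u = _flat(state.velocity).copy()
        n_it = 0
        for n_it in range(1, st.max_nonlinear_iterations + 1):
            if st.convection:
                b_nodal = np.stack([u[:self.nV] - _flat(w_new)[:self.nV],
                                    u[self.nV:] - _flat(w_new)[self.nV:]])
                C = asm.convection(b_nodal, rho, skew=True,
                                   upwind=st.upwind)
                K = A + C + (c0 / dt) * M
            else:
                C = None
                K = A + (c0 / dt) * M
            S = saddle_system(K, B, stab=stab)
            rhs = np.zeros(self._ntot)
            rhs[:2 * self.nV] = F + F_hist
            self._solver.factorize(S)
            x = self._solver.solve(rhs, vals)
            u_new = x[:2 * self.nV]
            delta = np.linalg.norm(u_new - u) / max(np.linalg.norm(u_new),
                                                    1e-30)
            u = u_new
            if not st.convection or delta <= st.nonlinear_tolerance:
                break
        # a large relative update between sweeps signals blow-up; with a
        # single sweep (semi-implicit mode) delta measures the step change
        # instead, so it is not a nonlinear-convergence indicator
        if st.convection and n_it >= 2 and (not np.isfinite(delta)
                                            or delta > 0.5):
            raise RuntimeError(
                f"Picard iteration diverging at t={state.time + dt:.4f}s: "
                f"relative update {delta:.2e} after {n_it} iterations"
            )
        p = x[2 * self.nV:2 * self.nV + self.nQ]
        if self._zero_mean:
            mp = asm.pressure_mean()
            p = p - (mp @ p) / mp.sum()

        # boundary momentum residual -> consistent wall traction data
        r = K @ u + B.T @ p - F - F_hist
        reactions = np.stack([r[:self.nV], r[self.nV:]], axis=1)
        if not np.all(np.isfinite(u)):
            raise RuntimeError("flow solve produced non-finite velocities")
        return FlowState(
            velocity=np.stack([u[:self.nV], u[self.nV:]], axis=1),
            pressure=p,
            mesh_displacement=coords_new - self.mesh.points,
            mesh_velocity=w_new,
            time=state.time + dt,
            wall_reactions=reactions,
            boundary_mass=asm.facet_lumped_mass(),
        )


def advance_flow(state: FlowState, mesh: Mesh, coords_new: np.ndarray,
                 w_new: np.ndarray, props: FluidProperties,
                 settings: SolverSettings, dt: float,
                 state_prev: FlowState | None = None) -> FlowState:
    """One implicit ALE step (convenience wrapper around :class:`FlowSolver`)."""
    return FlowSolver(mesh, props, settings).advance(
        state, coords_new, w_new, dt, state_prev=state_prev)


# ---------------------------------------------------------------------------
# cycle orchestration
# ---------------------------------------------------------------------------


def run_cycles(mesh: Mesh, preset: kin.BreathingPreset, spec: CavitySpec,
               props: FluidProperties | None = None,
               settings: SolverSettings | None = None,
               motion_settings: kin.MeshMotionSettings | None = None
               ) -> FlowHistory:
    """Drive the cavity for ``preset.n_cycles`` breathing cycles from rest.

    Each step: prescribe the isovolumetric boundary motion, propagate it
    elastically, difference it in time for the wall/mesh velocity, then take
    one implicit ALE Navier-Stokes step with ``u = w`` on all walls.
    Snapshots (with wall-reaction data for WSS extraction) are recorded at
    ``settings.snapshot_stride``; cycle-to-cycle periodicity residuals are
    reported at the end of every cycle after the first.
    """
    props = props or FluidProperties()
    settings = settings or SolverSettings()
    T = preset.period
    dt = settings.dt if settings.dt is not None else T / settings.steps_per_cycle
    steps_per_cycle = int(round(T / dt))
    if abs(steps_per_cycle * dt - T) > 1e-9 * T:
        raise ValueError("dt must divide the forcing period")
    if steps_per_cycle % settings.snapshot_stride:
        raise ValueError("snapshot_stride must divide steps per cycle")

    V0 = compute_volume(mesh)
    mm = kin.MeshMotionSolver(mesh, motion_settings)
    solver = FlowSolver(mesh, props, settings)
    vspace = solver.asm.V

    nondim = diagnostics(mesh, preset, props)
    log.info("run_cycles: %s", ", ".join(f"{k}={v:.3g}"
                                         for k, v in nondim.items()))

    history = FlowHistory(
        mesh=mesh, preset=preset, settings=settings, props=props,
        snapshots_per_cycle=steps_per_cycle // settings.snapshot_stride,
    )
    state = solver.initial_state()
    prev_state: FlowState | None = None
    disp_hist: list[kin.DisplacementField] = [
        kin.DisplacementField(np.zeros_like(mesh.points), 0.0, None)
    ]
    n_steps = steps_per_cycle * preset.n_cycles
    bdf2 = settings.time_scheme == "backward_difference_2"

    for n in range(1, n_steps + 1):
        t = n * dt
        if preset.amplitude > 0:
            bnd = kin.prescribed_boundary_motion(mesh, preset, spec.z_ov, t)
            dvol = mm.solve(bnd)
        else:
            dvol = kin.DisplacementField(np.zeros_like(mesh.points), t, None)
        disp_hist.append(dvol)
        if len(disp_hist) > 3:
            disp_hist.pop(0)
        scheme = ("backward_difference_2"
                  if bdf2 and len(disp_hist) >= 3 else "backward_difference_1")
        w_vertex = kin.mesh_velocity(disp_hist, dt, scheme)
        coords_new = mesh.points + dvol.values
        w_nodal = _to_velocity_nodes(vspace, w_vertex)
        try:
            new_state = solver.advance(
                state, coords_new, w_nodal, dt,
                state_prev=prev_state if bdf2 else None)
        except RuntimeError as exc:
            raise RuntimeError(f"step {n} (t={t:.4f}s) failed: {exc}") from exc
        prev_state, state = state, new_state

        vol_now = compute_volume(mesh.displaced(dvol.values))
        if abs(vol_now - V0) > 5e-3 * V0:
            raise RuntimeError(
                f"volume drift {abs(vol_now - V0) / V0:.2e} at t={t:.3f}s "
                "exceeds the isovolumetry tolerance")
        if n % settings.snapshot_stride == 0:
            history.states.append(state)
        if n % steps_per_cycle == 0:
            cyc = n // steps_per_cycle
            if cyc >= 2:
                res = periodicity_residual(history, cyc - 1, cyc)
                history.periodicity_residuals.append(res)
                log.info("cycle %d periodicity residual %.3e", cyc, res)
    return history


def _flat(v: np.ndarray) -> np.ndarray:
    """(n, 2) nodal field -> blocked [all x; all y] vector."""
    return np.concatenate([v[:, 0], v[:, 1]])


def _to_velocity_nodes(vspace, vertex_field: np.ndarray) -> np.ndarray:
    """Interpolate a per-vertex field to velocity nodes (P2 edge midpoints)."""
    if vspace.degree == 1:
        return vertex_field
    mids = vertex_field[vspace._edges].mean(axis=1)
    return np.vstack([vertex_field, mids])


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def diagnostics(mesh: Mesh, preset: kin.BreathingPreset,
                props: FluidProperties) -> dict:
    """Nondimensional numbers of the forcing: Reynolds, Womersley, CFL scale."""
    L = float(mesh.points[:, 0].max() - mesh.points[:, 0].min())
    U = preset.amplitude * 2 * np.pi * preset.frequency  # velocity scale
    nu = props.kinematic_viscosity
    return {
        "reynolds": U * L / nu,
        "womersley": 0.5 * L * np.sqrt(2 * np.pi * preset.frequency / nu),
        "forcing_speed_m_s": U,
    }


def divergence_norm(state: FlowState, mesh: Mesh,
                    velocity_degree: int = 2) -> float:
    """||div u|| / ||grad u|| over the displaced domain (0/0 -> 0)."""
    asm = Assembler(mesh, velocity_degree=velocity_degree)
    asm.set_coords(mesh.points + state.mesh_displacement)
    u = _flat(state.velocity)
    cd = asm.V.cell_dofs
    gx = np.einsum("eqa,ea->eq", asm.Gv[..., 0], u[:asm.V.ndof][cd])
    gy = np.einsum("eqa,ea->eq", asm.Gv[..., 1], u[asm.V.ndof:][cd])
    hx = np.einsum("eqa,ea->eq", asm.Gv[..., 0], u[asm.V.ndof:][cd])
    hy = np.einsum("eqa,ea->eq", asm.Gv[..., 1], u[:asm.V.ndof][cd])
    div2 = float((asm.w * (gx + gy) ** 2).sum())
    grad2 = float((asm.w * (gx ** 2 + gy ** 2 + hx ** 2 + hy ** 2)).sum())
    if grad2 == 0.0:
        return 0.0
    return np.sqrt(div2 / grad2)


def periodicity_residual(history: FlowHistory, cycle_a: int | None = None,
                         cycle_b: int | None = None) -> float:
    """Relative L2 velocity difference between matching phases of two cycles.

    Defaults to the last two recorded cycles; this is the quantitative
    surrogate for "ran to a periodic (statistically steady) state".
    """
    n = history.n_cycles_recorded()
    if n < 2:
        raise ValueError("periodicity residual needs at least 2 full cycles")
    if cycle_b is None:
        cycle_a, cycle_b = n - 1, n
    ua = np.stack([s.velocity for s in history.cycle_states(cycle_a)])
    ub = np.stack([s.velocity for s in history.cycle_states(cycle_b)])
    denom = np.linalg.norm(ub)
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(ua - ub) / denom)
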