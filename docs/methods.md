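# Methods

`asciflow` estimates the fluid currents and wall shear stresses (WSS/FSS)
that cyclic diaphragmatic excursion drives through an ascites-filled
peritoneal cavity, and inverts a companion perfusion-bioreactor model to
find pump settings that reproduce chosen shear levels on an embedded cell.
This note records the model, its assumptions, the defaults and why they
were chosen, the numerical treatment, and what the synthetic test problems
do and do not demonstrate.

## Synthetic cavity geometry

Rather than depending on a patient-derived fluid segmentation, the cavity
is a synthetic stand-in that preserves the features the forcing model needs:
an enclosed fluid domain of ascites scale with

- a deformable top surface (`diaphragm`),
- vertical side walls (`lateral`),
- a fixed bottom (`floor`), and
- two spherical-cap protrusions on the floor (`ovary_left`, `ovary_right`)
  on which WSS is reported.

The full 3D domain is a box with spherical-cap floor bumps; the first-class
desk model is its vertical mid-plane cross-section (circular-arc bumps).
Coordinates: `z` is cranio-caudal with `z = cavity_height` at the
diaphragm; SI units internally, cm/s and dynes/cm² (1 Pa = 10 dynes/cm²)
only at reporting.

Defaults (all configurable in `CavitySpec`): height 0.40 m, width 0.30 m,
depth 0.20 m — torso-scale so the 6–8 cm diaphragm excursions remain a
moderate fraction of the cavity height; ovary radius 3 cm with centres
0.5 cm below the floor plane (cap height 2.5 cm), reference height
`z_ov = 4 cm`. Giving `target_volume` instead (e.g. 2.5 L, a severe-ascites
scale) sizes the box through fixed aspect ratios; the realized mesh volume
lands within 2% of the request. Meshing is a structured crossed-triangle
(or 6-tet-per-hex) grid with the floor profile folded into the vertical
coordinate map, which keeps generation deterministic, exactly
mirror-symmetric about `x = 0`, and free of external mesh generators.
Optional interior-vertex jitter (seeded) is available for
mesh-sensitivity checks and is off by default.

## Breathing kinematics

The diaphragm forcing is kinematic, not mechanical: the top boundary moves
vertically with amplitude `A` and frequency `f` (`regular`: 6.0 cm at
0.37 Hz; `active`: 8.0 cm at 1.0 Hz; runs last three cycles by default).
The excursion decays linearly from the top of the ascites (weight 1) to the
ovary height `z_ov` (weight 0); everything at or below `z_ov` is held
stationary. The time profile `s(t)` is a raised cosine
`(1 − cos 2πft)/2` — the amplitude/frequency pair does not determine a
waveform, and the raised cosine starts from rest (`s(0) = ṡ(0) = 0`), so a
fluid initially at rest is consistent with the walls. A plain `sine`
alternative is available. The excursion direction is downward
(compression); it is configurable.

Because the cavity is closed and the fluid incompressible, the prescribed
motion must preserve the enclosed volume or the no-slip problem is
ill-posed. Volume is restored by an equal lateral deformation: a single
magnitude `g(t)`, weighted by the same vertical profile, applied as a
horizontal dilation of the boundary — uniform outward/inward normal motion
on the lateral walls, linearly interpolated across the diaphragm so the
boundary field stays continuous at the wall/top corners (a discontinuous
corner field inverts mesh elements). `g(t)` is found by bracketed
root-finding (Brent) on the enclosed volume of the displaced boundary,
computed exactly for straight facets via the divergence theorem, seeded by
the first-order estimate `deficit / effective lateral area`. The residual
volume defect is at root-finder tolerance (~1e-15 relative), far below the
1e-3 isovolumetry requirement the solver assumes.

An alternative reading of "equal lateral deformations" — lateral magnitude
equal to the vertical amplitude — does not preserve volume on a general
cavity and was not adopted.

The boundary field is propagated into the volume by a linear elastic
pseudo-solid solve (constant-strain P1 simplices, ν = 0.3, E arbitrary
since only ratios matter, Dirichlet on the whole boundary). Element
stiffness is optionally scaled by `(mean volume / element volume)^χ`
(`stiffening_exponent`, default 1) so small cells near the ovary bumps
resist inversion. Displacements are always solved from the undeformed
reference configuration, so the operator is factorized once per run; this
also makes the mesh position a pure function of time (no path dependence).
Mesh velocity is the backward difference of the displacement at the same
order as the flow time integrator.

## Flow solve

Incompressible Newtonian ALE Navier–Stokes on the moving mesh:

    ρ (∂u/∂t|mesh + ((u − w)·∇)u) = ∇·(−pI + μ(∇u + ∇uᵀ)),   ∇·u = 0,

with `u = w` (no slip) on every wall and fluid properties
ρ = 1017.5 kg/m³, μ = 0.0012 Pa·s (ascitic fluid, essentially slightly
hyperdense saline). Discretization choices, none of which are dictated by
the physics alone:

- **Elements.** Taylor–Hood P2/P1 triangles by default (inf-sup stable, no
  tuning); equal-order P1/P1 with Brezzi–Pitkäranta pressure stabilization
  (coefficient 0.05 h²/μ) as a cheaper alternative. The flow solver
  operates on the 2D cross-section and axisymmetric modes; 3D meshes are
  supported by the geometry and kinematics layers but a 3D Navier–Stokes
  solve is beyond the desk scale this package targets.
- **Time.** Implicit BDF1 (default) or BDF2, 200 steps per forcing cycle by
  default (100 in the desk profile `SolverSettings.desk()`). Fields are
  attached to mesh nodes (node-following ALE), so the nodal time
  difference *is* the ALE derivative; mass, viscous and convective
  operators are assembled on the new configuration with `w` from the
  matching backward difference. A rigid translation of a co-moving fluid
  is then preserved to solver precision (the discrete geometric-
  conservation check; measured ≲ 1e-11).
- **Convection.** Picard linearization in skew-symmetric form
  (`(b·∇)u + ½(∇·b)u`), which makes the discrete convective operator
  energy-neutral and the implicit step unconditionally stable. At desk
  resolutions the breathing flows reach Reynolds numbers of order 1e4–1e5,
  far beyond what the mesh resolves; an energy-neutral Galerkin scheme
  then sloshes indefinitely instead of settling. Classical streamline-
  upwind diffusion `τ_e (b·∇u, b·∇v)` with `τ_e = ρ h_e/(2|b|)` (an
  effective streamwise viscosity `|b| h_e/2`, `upwind` coefficient
  default 1) supplies the missing subgrid dissipation. The term vanishes
  identically wherever `b·∇u = 0`, so the Poiseuille, Womersley and
  uniform-translation verification flows are untouched by it.
  With `max_nonlinear_iterations = 1` the scheme is the standard
  semi-implicit (lagged-convection) method — the desk profile uses this;
  more sweeps tighten the nonlinear residual at proportional cost.
- **Pressure.** All-Dirichlet velocity BCs leave pressure defined up to a
  constant. The linear solve pins one pressure dof (keeping the matrix
  fully sparse — a dense zero-mean constraint row was measured to inflate
  the LU fill-in roughly tenfold); the reported pressure is then shifted
  to zero mean. WSS is computed from the full stress and projected
  tangentially, so it is invariant to this constant by construction.
- **Linear algebra.** Sparse LU (SuperLU, COLAMD ordering) on the saddle
  system; numpy-vectorized assembly with degree-5 (7-point) triangle
  quadrature throughout.

"Steady state" is operationalized as the relative L2 difference of the
velocity between matching phases of consecutive forcing cycles (the
periodicity residual); the 5% steady-state threshold used in the checks is
this package's choice. On the desk cavity both presets reach ~1–2% by cycle 3,
with cycle-3-vs-2 below cycle-2-vs-1.

## Wall shear stress and cycle metrics

Wall traction is recovered variationally ("consistent flux"): the solver
saves the boundary rows of the discrete momentum residual — equal to the
integral of σ·n against each boundary test function, including inertia and
convection — and division by the lumped boundary mass yields nodal traction
vectors. On simplex meshes this is markedly more accurate than
differentiating the velocity at the wall (the stabilized-P1 Poiseuille
case converges at second order in the wall shear, where direct nodal
gradients are first order). FSS is the tangential projection
`τ_w = t − (t·n)n` with area-weighted nodal normals; nodes of zero surface
measure (the poles of the axisymmetric sphere) are excluded. For fixture
states without solver residuals the steady Stokes residual `A u + Bᵀ p` is
assembled instead, which is exact for hydrostatic and uniform-shear fields.

Reported metrics, each defined in its most standard sense (the definitions
change the numbers and are therefore stated prominently):

- **mean FSS** per ovary: area-weighted spatial mean of `|τ_w|`, then
  time-averaged over the snapshots of the final forcing cycle;
- **peak FSS** per ovary: maximum over boundary nodes and snapshot times of
  the final cycle (a true maximum, not a percentile);
- **mean speed**: volume-weighted average of `|u|` (quadrature on the
  displaced mesh), time-averaged over the final cycle; **peak speed**:
  maximum over velocity nodes and snapshots. Speeds print in cm/s, FSS in
  dynes/cm².

## Bioreactor model

Two decoupled stages mirror the device physics:

1. **Hydrogel plug (Brinkman).** Pump flow divides over 8 radial chambers;
   each plug is a porous medium with permeability k (default 1e-14 m², a
   dense-agarose scale) and porosity 0.85, effective viscosity
   μ_eff = μ/φ (a common closure, stated openly). The inflow is
   flow-rate-controlled: the discrete inlet profile is scaled so the
   numerical flux equals Q per chamber exactly, and the volume-averaged
   axial speed — identical to the superficial speed by mass conservation —
   is passed to stage 2. A closed-form Darcy fast path returns the
   superficial speed directly and is appropriate whenever the Brinkman
   screening length √(k/φ) (≈ 0.1 µm at the defaults) is far below the
   mesh scale.
2. **Idealized cell in an open channel.** A semicircular bump (2D default;
   radius 7.5 µm) on the floor of a 100 µm channel under fully developed
   inflow of mean speed U. At bioreactor speeds the cell-scale Reynolds
   number is ≪ 1, so the steady Stokes equations are solved (a warning is
   logged if Re > 0.1). The FSS profile over the cell's arclength, its
   peak, and the flat-wall reference 6μU/h are returned. The peak sits on
   the bump crest and exceeds the flat-wall value by a geometry-dependent
   amplification factor (an output, ~3 at the default geometry).

**Inverse design.** Stokes linearity makes peak FSS exactly proportional
to U, so one forward solve fixes the slope and the operating point for a
target FSS (1, 5, 11 dynes/cm² — interstitial, average-ascitic and
elevated-ascitic levels) is a division; a verification solve confirms the
≤ 1% residual, and the pump rate follows from the superficial-speed
relation. The cell and chamber dimensions are documented placeholders —
the physical device's values are not in the public record — so the
returned operating points are exercised for their structural properties
(forward/inverse consistency, 1:5:11 speed ratios, mesh convergence of the
peak), not compared to device settings.

## Verification suite and what it shows

Six registered cases (`asciflow verify`): plane-Poiseuille wall shear
(vs 6μU/h, stabilized pair, three refinements, observed order ≈ 2);
oscillatory channel flow at 0.37 Hz vs the analytic complex-exponential
solution (Womersley number ≈ 4.2; velocity L2 and WSS amplitude within a
fraction of a percent at desk resolution); axisymmetric creeping flow past
a sphere vs the classical peak WSS (3/2)μU/a (the analytic field is the
outer Dirichlet data; peak error ≈ 2–3% on the finest shell); enclosed-
volume drift through a breathing cycle (≈ machine precision); uniform-
translation preservation; and bioreactor Stokes linearity plus peak-FSS
mesh convergence. A green suite establishes that the discretization,
moving-mesh treatment and WSS extraction are correct.

What it does **not** show: the synthetic cavity is not a patient anatomy.
The 2D cross-section exaggerates lateral wall motion (volume compensation
is shared by two wall segments instead of a full perimeter), omits
out-of-plane transport, and its under-resolved high-Reynolds dynamics are
regularized by the streamline-upwind viscosity. Desk-run velocity and FSS
metrics therefore carry the right orders of magnitude and the right
orderings (energetic > quiet breathing in every metric), not
patient-specific values.

## Numerical edge cases and known limitations

- Degenerate geometry (non-positive lengths, ovary spheres not protruding
  through the floor, `z_ov` above the cavity) is rejected at construction;
  inverted cells are reported by index, and mesh-motion inversion failures
  advise raising `stiffening_exponent` or lowering the amplitude.
- With a mirror-symmetric cavity, the quiet-breathing run keeps left/right
  ovary metrics equal to well under 1%. The energetic run is chaotically
  sensitive at its effective Reynolds number: roundoff-seeded asymmetry
  amplifies over three cycles to a few percent in the time-mean and up to
  ~10% in the node/time maximum, and is not monotone in the dissipation
  coefficient. Symmetry should be assessed on the quiet run (or in Stokes
  test mode, where it holds to solver precision).
- Desk problem sizes (package defaults chosen once): cavity 20×27 crossed
  grid (2160 triangles, ~10k velocity+pressure dofs), 100 steps per cycle,
  3 cycles; sphere shells up to 96×36; cell channel ~5k triangles. A
  three-cycle cavity run takes on the order of 100 s on one core.
- The linear-elastic mesh motion is solved from the reference
  configuration in one shot; it is not guaranteed inversion-free for
  arbitrary amplitude/geometry combinations (it is, with margin, for both
  presets on the default cavity).
- Only the constant-rate (steady) bioreactor design model is implemented;
  pulsatile waveforms of the physical pump are out of scope, as are
  hydrogel poro-elasticity and nutrient transport.
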