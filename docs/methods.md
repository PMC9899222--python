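# Methods

This note documents the models, numerical methods, parameter defaults and
known limitations of `radonroom`, in the order the pipeline runs them.

## Room geometry and grids

The domain is a rectangular room, default 3.0 m (W, x) × 4.0 m (L, y) ×
2.8 m (H, z), volume 33.6 m³, with a 1.2 × 0.8 m window (0.96 m²) and a
1.0 × 2.2 m door. The window is centred on the x = Lx wall; the door sits
on the y = 0 wall flush to the left with a 0.1 m reveal (x ∈ [0.1, 1.1] m).
Exact in-wall positions are not critical to the volume-averaged results
and are configurable. Coordinates are physical metres from the room
corner, so the detector position A (2.9, 0.1) lies near the x = 3 / y = 0
corner.

Two door scenarios: *open* (the whole door is a pressure outlet) and
*closed* (the door leaf is a no-slip wall; only an under-door gap,
default height 0.03 m, vents the room — a closed door still lets air
through at its bottom, which is what keeps the closed-room problem
well-posed).

Grids are uniform Cartesian; a resolution is either cells-per-metre or an
explicit (nx, ny, nz). Patch rectangles snap to the nearest face
boundaries. A patch thinner than one cell spacing — the under-door gap at
any realistic resolution — receives exactly one face row rather than an
error: the gap's *area* is then grid-limited, which only rescales the
outlet velocity, not the ventilation flow (the outlet is a pressure
boundary). The inlet speed applied to the snapped window is rescaled so
the volumetric flow equals ACH·V/3600 exactly regardless of snapping.

## Air and ventilation

Inlet speed: U_in = ACH·V/(A·3600); the default room at 1 ACH gives
0.0097 m/s. Humid-air density is the ideal-gas mixture of dry air and
vapour with the Magnus-type (Alduchov–Eskridge) saturation correlation;
viscosity is Sutherland's law for dry air (the RH effect on μ is < 1% and
neglected). Default state 24 °C, RH 50%, 101325 Pa.

A note on regime: with U_in ≈ 0.01 m/s and the window hydraulic diameter
(0.96 m) the inlet Reynolds number is ≈ 620; no obvious room length scale
pushes it past the turbulent threshold. The package computes Re but does
not gate the closure choice on it.

## Flow solver

SIMPLE pressure–velocity coupling on a staggered grid:

* Momentum: finite-volume, hybrid central/upwind scheme (first-order
  upwind selectable), under-relaxed Jacobi sweeps (α_u = 0.7, 4 sweeps
  per outer iteration). The net-outflux term in the diagonal is clipped
  at zero so the matrix stays an M-matrix while continuity is still
  converging; the term vanishes at convergence.
* Pressure correction: a seven-point Poisson matrix with *fixed*
  diffusion-based face coefficients, factorised once per run (sparse LU)
  and reused every iteration. Because the velocity corrections use the
  same coefficients as the matrix, the corrected field satisfies discrete
  continuity exactly each iteration irrespective of how well those
  coefficients approximate the true momentum diagonal — the approximation
  affects only the convergence rate. When the effective viscosity departs
  from the build-time value (k–ε closure), the *pressure accumulation* is
  rescaled by the viscosity ratio to avoid over/under-shooting;
  α_p = 0.3.
* Outlets: zero-gradient velocity with a zero-pressure ghost; outlet
  fluxes are rescaled to the inlet flow every iteration, so the global
  mass balance is exact by construction and the per-cell divergence
  converges below tolerance (default 10⁻⁶ relative, the successive-
  iteration criterion).
* Walls: no-slip via wall-shear folding (2μA/δ); free-slip and
  tangentially moving walls are supported for verification presets.
  Closed domains (no outlet) pin the pressure level.
* Flow is isothermal with no body forces: the room is assumed thermally
  homogeneous, so buoyancy is excluded by construction.

Verification: the quasi-2D lid-driven cavity preset (free-slip span) at
Re = 100 on a 48² grid matches the published benchmark centreline values
(u_min, u at mid-height, v extrema) within 0.3–2.5%, and a symmetric
room configuration yields an x-mirror-symmetric field to solver
tolerance.

### Turbulence closure

Default: **constant effective viscosity** with the zero-equation
ventilation estimate ν_t = 0.03874·U_in·H (H the room height), i.e.
ν_eff ≈ 1.1×10⁻³ m²/s for the default room at 1 ACH. This level of
mixing is the standard engineering estimate for mechanically gentle room
airflow and makes the steady problem well-conditioned.

Optional: **standard k–ε** (C_μ = 0.09, C1 = 1.44, C2 = 1.92, σ_k = 1.0,
σ_ε = 1.3) with log-law equilibrium dissipation in wall-adjacent cells
and inlet turbulence of 5% intensity, length scale 0.07 × opening size.
At desk-scale resolution (0.1–0.2 m cells) and centimetre-per-second
velocities the wall cells sit far below the log-law validity range and
the predicted μ_t collapses below the stability threshold of the steady
coupled iteration. Three numerical safeguards keep the closure usable:
realisability bounds on k (capped at 10 U_ref²) and ε (mixing length
bracketed in [H/1000, H]), a stabilising floor μ_t ≥ 0.25 × the
zero-equation value, and the pressure-update rescaling above. The k–ε
option is therefore a qualitative companion at this scale, not a
boundary-layer-resolving model; μ_t in the room bulk sits mostly at the
floor. The fully-developed-channel regime where wall functions are
quantitative is outside what these grids resolve, and no claim is made
for it.

## Radon transport

Conservative finite-volume discretisation of
0 = S + ∇·(Γ∇C) − ∇·(UC) − λC with first-order upwind advection
(positivity-preserving), central diffusion with Γ = D + ν_t/Sc_t
(Sc_t = 0.7), and implicit decay. With the flow frozen the system is
linear and solved directly (sparse LU); the steady activity balance
(sources + inlet advection − outlet advection − decay) closes to
rounding, far below the 10⁻⁴ contract.

Boundary conditions: the ventilation inlet carries a purely advective
influx at the outdoor concentration C_out (total-flux condition — no
diffusive exchange with the boundary value). For upwind advection this
coincides with a Dirichlet inlet in the advective term; retaining a
diffusive link to C_out would, in the strong-mixing limit, clamp the
whole room to the outdoor level instead of the ventilation balance, which
is unphysical for an opening that only admits outdoor air. Outlets are
advective outflows with zero diffusive flux. Walls are zero-flux, or
carry the prescribed exhalation flux in `boundary_flux` mode.

Two source modes, never mixed silently:

* `boundary_flux` — each solid surface emits E_i (default 3.1
  Bq m⁻² h⁻¹, the measured cement exhalation rate); this is the physical
  picture and produces the floor-adjacent enrichment seen in measurements.
* `volumetric` — a uniform G (Bq m⁻³ h⁻¹); by default the
  exhalation-derived G = ΣE_iA_i/V = 5.83 Bq m⁻³ h⁻¹ for the default
  room, or an explicit (e.g. calibrated) value.

**Source calibration.** The analytical ventilation-sweep table implies an
effective generation rate G ≈ 65.2 Bq m⁻³ h⁻¹ (obtained by inverting the
steady single-zone balance at ACH = 0.3), roughly 11 × the value the
exhalation measurement yields. The package surfaces both numbers and
never averages or blends them: `calibrate_generation` inverts the
balance, the sweep-reproduction path uses the calibrated G, and the
physical-source path uses E_i. The discrepancy is inherited from the
source data, not resolved here.

Point sampling is trilinear on cell centres, with positions inside the
boundary half-cells clamped to the nearest centre plane (a detector
against a wall reads the adjacent air).

Verification: a manufactured Taylor–Green velocity / cosine concentration
pair with analytically derived source converges at first order (L2 error
ratio ≈ 2 per 2× refinement), and the strong-diffusion limit reproduces
the well-mixed steady value to < 0.1%.

## Well-mixed model and dose

Single-zone balance dC/dt = G + λ_V(C_out − C) − λ_Rn·C, λ_Rn =
7.56×10⁻³ h⁻¹ (2.1×10⁻⁶ s⁻¹). The outdoor-inflow term is on by default:
with it, a single-point calibration at ACH = 0.3 reproduces the entire
published analytical sweep (138.22, 74.59, 53.17, 42.42, 25.11 Bq m⁻³)
to ±0.01, and the high-ACH limit approaches C_out as it must. The
textbook form without the outdoor term is available behind a flag.

Dose: AED = C·F·t·K with F = 0.4 (UNSCEAR indoor equilibrium factor),
t = 2000 h/yr occupancy, K = 12 nSv/(Bq·h·m⁻³) (ICRP 115), reported in
mSv/yr. Printed two-decimal reference values are honoured within a
±0.01 mSv rounding band (e.g. 0.674 computed vs 0.68 quoted).

## Synthetic data

The generator provides (a) the reference-room fixture (geometry,
ventilation, sources, and the published detector tables as data), (b)
manufactured solver-verification cases as above, and (c) synthetic
detector readings: ground-truth samples perturbed by multiplicative
lognormal noise, σ = 10% by default — typical of passive track-detector
uncertainty. All randomness flows through one seeded generator; the CLI
makes the seed mandatory. For small σ the mean relative deviation of such
readings is σ√(2/π) ≈ 7.98% at σ = 10%, which the comparison stage
reproduces over 10⁴ replicates.

What the synthetic detectors do *not* emulate: detector physics (track
formation, chamber response, humidity sensitivity), calibration-factor
uncertainty, or temporal averaging. Passing tests therefore show the
comparison arithmetic and the sampling chain are correct, not that real
detectors behave lognormally.

## Comparison metrics

Two deliberately distinct operations: the signed percentage difference
(analytical − numerical)/analytical × 100 used for the ventilation sweep,
and the absolute relative deviation |measured − predicted|/predicted ×
100 used for detector validation. Published table "Average" rows are
recomputed as the arithmetic mean of the listed cells and reported
alongside the printed values (which occasionally differ by rounding);
fixtures are never overwritten. Maxima are recomputed and flagged rather
than asserted from quoted summaries.

## Problem sizes and defaults

The flagship configuration runs 30 × 40 × 28 = 33,600 cells (10 cells/m),
converging in ≈ 370 SIMPLE iterations (~35 s on one CPU); property and
sweep tests use 5 cells/m (4,200 cells, ~1 s per flow solve). These sizes
were chosen as the natural desk-scale working points: the volume-averaged
concentration changes by well under a percent between them, consistent
with the plateau of the mesh-convergence study the workflow is built
around. Cell-for-cell agreement with a megacell unstructured commercial
solve is not expected at this scale; model-level agreement (volume
averages within a few percent, the correct spatial trends) is.

## Known limitations

* No buoyancy/thermal stratification, no transient meteorology, no
  progeny attachment/deposition or thoron.
* First-order upwind advection of radon adds numerical diffusion of
  order U·Δx/2 (~5×10⁻⁴ m²/s at the flagship grid), comparable to the
  turbulent diffusivity; spatial gradients are therefore smoothed
  relative to a second-order scheme, though volume averages are barely
  affected.
* The k–ε option is stabilised for coarse grids as described and should
  not be read as a wall-resolved turbulence model.
* The relative-humidity dependence enters only through air properties
  (density, and Γ indirectly); the non-monotonic concentration-vs-RH
  behaviour reported from species-transport models with humidity physics
  is out of scope.
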