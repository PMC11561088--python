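# Methods

`serpmix` models the mixing of a polymer solution (PLGA at 7 mg/mL in
acetonitrile, "ACN-PLGA") with an aqueous anti-solvent (TRIS buffer) inside a
glass serpentine micromixer, and derives from the solved fields the quantities
that matter for nanoprecipitation: where in the chip the polymer can nucleate
(area of precipitation), for how long the forming nuclei stay in that region
(residence times), and how homogeneous the mixture is along the channel
(mixing index and efficiency).  This note records the models, the defaults,
and the design choices where the problem was genuinely open.

## Chip model

The chip is a planar channel of constant width w = d = 200 μm and depth
h = 100 μm: two inlet arms (L1 = 1500 μm) meet at a Y-junction, followed by a
serpentine body of 15 straight runs joined by circular bends.  The default
layout maps the dimension table onto the path as: straight #1 of length
L2 = 2500 μm (horizontal; its midpoint is the unmixed reference section), one
90° bend of radius R2 = 800 μm, straight #2 of L3 = 5600 μm, then 13 straights
of L4 = 13000 μm joined by 13 alternating 180° U-bends of radius R1 = 800 μm.
The main-channel centerline is then 0.2110 m long.  The published drawing does
not state the mapping in text, so `ChipSpec` accepts an explicit
`segment_sequence`; the default was fixed by cross-checking independent
consequences of the candidate readings before any tuning: with this layout the
0D model puts the working point 0.2 ml/min at ~600 mbar (below the 800 mbar
burst pressure, with the limit TFR just above the working point), and
closed-form diffusion estimates of the outlet mixing index (~71–75%), the
area of precipitation (~17%) and the median residence time (~0.8–0.9 s) all
land on the reported operating behaviour.  Shorter readings of the serpentine
straights fail all of these simultaneously.

Because the duct is shallow, smooth, and strongly laminar with no
secondary-flow structures, the 3D problem is reduced to 2D on the channel
mid-plane.  The solver therefore resolves the *width*-wise mixing physics;
depth-wise (Hele-Shaw) averaging corrections are intentionally out of scope.

### Mesh

The mesh is body-fitted and structured: transverse index (20 cells across the
200 μm width at the default 10 μm cell size) × streamwise index (~21k columns).
Straight columns are rectangles, bend columns are annular sectors, so the grid
is orthogonal everywhere (Cartesian in straights, polar in bends) and the wall
geometry is exact.  Cell areas, face lengths and centroids are computed in
closed form per column; the summed cell area equals the analytic planform area
d·S to round-off.

### The junction

The two inlet arms are part of the geometry, the outline and the 0D network,
but the 2D computational domain starts at the junction: the merged stream is
represented as a split co-flow inlet.  In the default (`developed`) model the
streams enter side by side with uniform normal velocity v̄ = TFR/(d·h) and
solvent mass fraction Y = 1 on a band whose width fraction equals the solvent
flow fraction a/(a+b) (the straddling face carries the exact flux-weighted Y,
so the flow-rate ratio is conserved to round-off).  This keeps the mesh a
single structured block.  The velocity profile develops within
~0.05·Re·D_h ≈ 150 μm, far upstream of the first measurement section at
1250 μm, and the dividing streamline settles at the flow-fraction position
automatically.  A second idealization (`merge`) gives each arm half the
merge-plane width at its own uniform speed 2·Q_i/(d·h) and lets the squeeze
of the weaker stream develop in-domain; the two bracket the real
angled-junction transition.  Full-scale comparison at the asymmetric
operating points shows the merge variant shifts the precipitation-area and
in-AoP velocity figures a few tenths further below the reference values
(e.g. AoP at 1:7: 0.39% vs 0.51%), so `developed` is the default.  Neither
variant resolves the few hundred μm around the physical Y-junction.
Mirroring the solvent band to the other lateral wall changes every reported
metric by under 1.5% relative (the precipitation band crosses bends of
alternating curvature), so the side convention is immaterial.  The physical
arm velocities (v = Q_i/(d·h)) are still computed and reported for each
operating point.

## 0D hydraulic network

Each channel portion is a series resistance.  Straights follow Hagen-
Poiseuille, Δp_s = 32 μ L v / D_h², with D_h = 2dh/(d+h) = 133.3 μm.  Bends
add a concentrated loss Δp_b = K ρ v²/2 with

    K = 32 R (0.026 · Dn · e^0.661 + 1) θ / (D_h · Re),

an approximation of the low-Reynolds bend-loss diagram of Ghia et al.; Dn =
Re·sqrt(D_h/2R) is the Dean number and θ the bend angle.  The printed form of
this correlation admits a second reading, `0.026·Dn^0.661 + 1` (a power law on
the log-log diagram); both are implemented behind `k_variant` and pinned by
regression tests, the literal reading being the default.  Water (1 cP)
characterizes the whole network by default.  Compliance, inertance and the
junction's own concentrated loss are neglected (rigid glass chip, creeping
velocities).  At FRR ≠ 1:1 the two inlet arms carry different flows; the
branch with the larger drop governs the total (the outlet pressure is common
and the pump limit is the worse branch) — a conservative choice with respect
to the burst pressure.

The limit TFR solves network_drop(TFR) = burst pressure (800 mbar) with
Brent's method on a doubling bracket; the drop is strictly monotone in TFR so
the root is unique.  For the reference chip and water the model gives
~600 mbar at 0.2 ml/min and a limit TFR of ~0.26 ml/min.

Note the 0D model describes the physical three-dimensional duct (through
D_h), while the 2D field solver describes the planform; their pressure drops
differ by a known geometry factor (32/D_h² vs 12/w² per unit length for the
straight portions).  `compare_0d_cfd` reports the signed relative difference
without asserting a fixed number.

## 2D finite-volume solver

Steady incompressible laminar flow and species transport in conservative
form:

    div(ρ v) = 0
    div(ρ v v) = −grad p + div(μ grad v)
    div(ρ v Y) = div(ρ D grad Y)

A `stokes` momentum mode drops the convective term (the creeping-flow
simplification grad p = μ ∇²v often quoted for microfluidics); the default
retains it, since Re = ρ v̄ D_h/μ ≈ 22 at the working point makes inertia
marginal but not negligible.  (The quoted "Re ~ 1" regime label for this chip
is not reproduced by these numbers; both values are logged and no attempt is
made to force agreement.)  The species equation as sometimes printed with a
positive diffusion term on the same side as convection would be
anti-diffusive; the standard conservative form above is solved.

Discretization: collocated finite volumes on the orthogonal structured grid.
Diffusion is central two-point (no cross-diffusion terms arise on an
orthogonal mesh).  Convection is implicit first-order upwind plus a deferred
second-order correction: gradient-based (Green-Gauss) second-order upwind for
momentum, and a dimension-by-dimension minmod MUSCL reconstruction for the
species — TVD along each grid line, so the converged mass fraction stays in
[0,1] to round-off at the sharp inlet front (any residual excursion from an
under-converged deferred loop is clipped and recorded).  Pressure–velocity
coupling uses momentum-interpolated (Rhie–Chow) face velocities, which
suppress checkerboard pressure modes on the collocated arrangement.  Two
algorithms are provided.  The default `coupled` algorithm assembles momentum
(pressure gradient implicit via Green–Gauss face averages) together with
continuity written on the momentum-interpolated face velocities — the face
pressure-difference part implicit, the lagged mean-gradient part explicit —
and solves the interleaved (u, v, p) system directly; on this long, thin
domain the system is banded with bandwidth 3·n_t + 2, a direct banded LU is
cheap, and only the convection/interpolation lag iterates, converging in
about ten outer iterations.  The segregated `simple` algorithm (classical
SIMPLE with under-relaxation 0.7/0.3 and the same Rhie–Chow fluxes) is kept
as an independent cross-check; it needs hundreds of iterations on the same
domain and agrees with the coupled solution to within the discretization's
own tolerance (the two differ only through the relaxation-dependent
Rhie–Chow dissipation scale, a known property of momentum interpolation).
All linear systems are solved with direct banded LU factorizations, so each
outer iteration is exact in its linear algebra and fully deterministic.

Boundary conditions: split co-flow inlet (fixed velocity and Y), no-slip
walls, zero-gauge outlet with upwind convective outflow (outlet fluxes are
rescaled to the exact inflow before each pressure correction; the converged
global imbalance is at round-off).  Fields are initialized with the developed
parabolic profile along the local tangent — deterministic, and exact away
from bends, so startup transients are local.

Convergence: scaled residuals (momentum scaled by ṁ·v̄, continuity by ṁ)
below `tol` = 1e-6 by default; non-convergence raises with the residual
history attached.  Under-relaxation (0.7 momentum / 0.3 pressure) acts as the
pseudo-transient continuation.  The species deferred-correction loop iterates
to 1e-9 (max-norm change) or 60 rounds; species conservation (flow-weighted
outlet mean vs inlet ratio) holds to ~1e-5 or better.

Mixture properties: Y-coupled by default, alternating flow and species
solves (Picard) with ρ(Y) from the ideal-mixture inverse-specific-volume rule
and μ(Y) linear in mass fraction; the blending law is a package choice (the
reference computation does not state one), and a linear-density switch
exists.  Intermediate Picard rounds converge the flow to a relaxed tolerance
(1e-4) since the property field they feed is provisional; a final round
polishes flow and species at the full tolerance.  A `constant` mode evaluates
the mixture at the blended inlet state and solves one-way, reproducing
`solve_flow` + `solve_species` exactly.

### Verification oracles

* Plane Poiseuille in a straight duct: transverse profile within 1% of the
  parabola (max/mean = 1.5 at the discrete cell centers), pressure gradient
  within 1% of 12 μ v̄/w².
* Species transport against an independent parabolized space-marching
  (FTCS) solution on a 20×-finer transverse grid: within 2% pointwise at a
  resolved front.
* Exact discrete conservation of mass and species; antisymmetry of Y about
  the centerline at FRR 1:1; bit-identical repeat solves.

## Metrics

* **Mixing index** per section j (15 sections at the midpoints of the
  straight runs, sampled at the 20 cell centers across the width):
  MI_j = (1 − sqrt(Var_j / Var_1))·100, with Var the population variance of
  the section samples about the *own-section* mean and section 1 the unmixed
  reference.  (A literal same-mean reading of the denominator degenerates to
  0/0 for fully mixed sections and is rejected.)  MI is clamped to [0, 100].
* **Mixing efficiency**: ME = (1 − N_unmixed/N_tot)·100 with unmixed meaning
  Y > 0.95, evaluated by default over the cumulative upstream region ending
  at each section (a per-section-only mode exists).
* **Area of precipitation**: AoP% = 100 · area(0.7 < X_ACN < 0.95)/area,
  strict bounds, evaluated on the ACN mass fraction X_ACN = Y·(1 − w_PLGA)
  with w_PLGA = 7/797 ≈ 0.88% (the PLGA loading of the solvent stream);
  numerically X_ACN ≈ Y but the distinction is kept exact.
* **Mixing time**: τ_mix = w²/(9·D·(1 + 1/FRR)²) with FRR the numeric
  anti-solvent:solvent ratio n of a 1:n run — higher dilution focuses the
  solvent stream and shortens τ_mix, consistent with the hydrodynamic-
  focusing origin of the formula.  For w = 200 μm and D = 3.5e-9 m²/s:
  0.317 s (1:1) to 0.972 s (1:7).
* **Residence time**: τ_i = L_i/v_i per AoP cell, with L_i the *centerline*
  distance from the cell's streamwise station to the outlet (a Euclidean
  distance is meaningless inside a serpentine) and v_i the centroid speed;
  stagnant cells are excluded with a warning and values below τ_mix are
  discarded.  The in-AoP velocity statistics are computed on the same
  τ_mix-filtered cell set as the residence times.  Percentiles use the
  inclusive linear-interpolation estimator (numpy default), making medians
  and IQRs bit-for-bit reproducible.

## Image validation

The validation pipeline mirrors a micrograph protocol: an ROI drawn on the
first image is reused for the aligned stack; the two dark channel borders are
the grayscale row minima (column-averaged over the central 50% of the ROI;
each detected row slides inward over a thick border band so the returned rows
are those adjacent to the interior; the second minimum must lie ≥ 5 px away
on the opposite side of the ROI midline); the RGB profile is read along the
transverse line at the ROI's horizontal center with the first and last 10 px
discarded (border shadow).  Simulated profiles are rendered through a
two-endpoint linear RGB colormap (the colors of the two unmixed solutions;
rhodamine-pink anti-solvent and near-transparent solvent by default,
overridable by measured values), 8-bit quantized as a contour-plot screenshot
would be, and resampled onto the same pixel grid.  The per-channel percentage
difference ε_ij = 100·(Ī_exp − Ī_num)/Ī_num is reported for the interior
sections (1..14) plus a BT.601 grayscale variant and the grand mean.

The synthetic-micrograph generator renders a horizontal channel band colored
by the mapped mass-fraction profile with dark borders, flat background, and
seeded additive Gaussian noise (sd 3 intensity counts by default — the order
of sensor noise in a well-exposed bright-field image).  What it emulates:
geometry, borders, shadowing margins, quantization, pixel noise.  What it
does not: optical blur, uneven illumination, refraction at the channel walls,
dye nonlinearity, misalignment.  A zero-noise round trip is therefore exact
(ε ≡ 0) by construction, and the noisy round trip shows only statistical
deviations — passing these tests validates the processing chain, not the
microscope model.

## Study conditions and problem sizes

The pipeline defaults are the study conditions: TFR 0.2 ml/min; FRRs 1:1,
1:3, 1:5, 1:7; fluid table ρ = 1000/797 kg/m³, μ = 1.0/0.5 cP, D = 3.5e-9
m²/s (TRIS / ACN-PLGA); 10 μm cells (≈ 422k cells for the reference chip).
The acceptance script solves FRRs 1:1, 1:3 and 1:7 at 10 μm with the default
coupled-property solver — the three operating points that carry the reported
headline quantities; the unit-test suite exercises the full-chip physics on
the same mesh for the two extreme FRRs and uses a 4-straight serpentine and a
straight duct for the oracle and contract tests.

## Known limitations

* 2D planform physics: no Dean vortices (they are 3D), no depth-averaged
  drag correction; mixing beyond the resolved diffusion is not modeled, so
  section-wise values carry the discretization's (small, grid-aligned)
  numerical diffusion.
* The junction is a co-flow idealization; the few hundred μm around the
  physical Y-junction are not resolved.  At strongly asymmetric flow ratios
  the whole precipitation window is a near-wall sliver beginning at the
  junction, so quantities dominated by that sliver inherit the idealization:
  the in-AoP velocity median at 1:7 computes ~20–25% below a
  junction-resolving reference, while area, mixing-index and residence-time
  figures stay within the expected reproduction band.
* The bend-loss correlation is a printed approximation of a diagram; both
  plausible readings are implemented but neither is validated against the
  original diagram here.
* Nucleation/growth kinetics are out of scope: AoP and τ_res characterize
  the hydrodynamic opportunity for precipitation, not the precipitate.
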