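# Methods

## Volumetric model

A skeletal reconstruction is decomposed into *functional units* — head,
neck (optionally subdivided `neck:1`, `neck:2`, … for a tighter fit
around the cervical series), trunk, tail, and upper arm / forearm / hand
/ thigh / shank / foot per side. Each unit pools the vertices of all its
bone meshes and receives one convex hull (Qhull, via
`scipy.spatial.ConvexHull`); the bones of a unit share a hull, adjacent
units are hulled independently, and no overlap subtraction is applied
between them. The total C_vol is the plain left-to-right float sum of
the per-unit hull volumes in manifest order; rounding (4 decimals, m³)
happens only when tables are written.

Hull volume is computed by the divergence theorem as a sum of tetrahedra
between each face and the vertex centroid. Because the mesh is convex
and the centroid interior, the unsigned per-face tetrahedron volume
equals the outward-oriented signed volume, so the result is independent
of input face winding — deliberate, since photogrammetric meshes have
unreliable winding. An open surface (any edge not shared by exactly two
faces) is a `TopologyError`; coplanar or collinear hull input is a
`DegenerateInputError`, never a silent zero-volume hull, because silent
zeros would corrupt segment totals. Containment is certified per unit:
every input point must lie inside its hull within 1e-8 of the
bounding-box diagonal.

An independent Monte-Carlo oracle estimates any convex mesh's volume by
uniform sampling in its bounding box with a half-space containment test
(estimate = hit fraction × box volume, SE = box_vol·√(p(1−p)/n), refused
below n = 1000). It exists purely for verification and never replaces
the analytic path.

Pose variants (min / pref / max articulations) are expressed
declaratively in the segment manifest as alternative meshes and/or
per-row rigid transforms — shared geometry is never mutated — so limb
volumes are identical across poses whenever limb meshes are shared.
Manifest transforms must be proper rigid (rotation determinant +1);
unit conversion (e.g. millimetre scans) is a separate per-row scale
factor. Internal units are metres and kilograms throughout.

## Mass regression and prediction intervals

Volume converts to mass through OLS of log₁₀(mass) on log₁₀(C_vol) over
a calibration set of extant taxa (n ≥ 3, all values positive). The point
prediction is the back-transformed linear predictor — median-unbiased,
with **no smearing correction**, matching standard practice in the
mass-estimation literature and producing the familiar asymmetric
intervals. The 95% prediction interval for a new observation uses a
t quantile with df = n − 2 (calibration samples are small):

    half-width = t · s · sqrt(1 + 1/n + (x₀ − x̄)² / Sxx)

applied in log₁₀ space and exponentiated at the endpoints. Empirical
coverage over simulated calibrations is checked to land in [0.93, 0.97]
at the 95% level.

Dermal armour is a variance-free additive constant: mean and both bounds
shift equally. DME multiplies mean, bounds and every component by
(sub FL / adult FL)³; it therefore composes exactly and preserves
ordering. Whether an armour value should itself be rescaled when a model
is expanded is left to the caller; the default keeps it constant.

### The two-point fixture calibration

The literature calibration behind the packaged *Stegosaurus* estimates
is published in supplementary sources, not shipped here. The package
instead provides a *fixture*: the exact power law through the (total
volume, hull-derived mass) anchors of the preferred (1.2800 m³, 1526 kg)
and expanded (3.3781 m³, 3711 kg) models, giving b ≈ 0.916 and
a ≈ 1.217×10³ kg·m⁻³ᵇ. It reproduces the published means closely but has
zero residual degrees of freedom, hence degenerate intervals; it is
documented as a consistency fixture, not a literature regression. The
`fit_power_law` entry point keeps its n ≥ 3 precondition; the fixture is
built by the separate `CalibrationFit.from_two_points` constructor.

### Limb equations as configuration

Published circumference equations (bivariate summed-circumference,
multivariate, femur-only forms) are **registry entries with provenance,
not hard-coded constants**: their coefficients are facts of the cited
literature, some in modified supplementary forms, so the shipped
registry contains unconfigured stubs that raise with their citation
until the user supplies coefficients, plus one fully configured
synthetic example. Supported PI methods per equation: a log₁₀-space
residual half-width (normal, or t when a df is declared) or a symmetric
percent prediction error. Gram-valued equations are converted to kg at
the boundary. The optional integration test
`tests/test_acceptance.py::test_literature_coefficient_predictions`
activates when `config/literature_coefficients.yaml` exists at the
repository root, checking the published 3745 / 3752 / 1823 / 2158 kg
values against user-supplied coefficients.

## Inverse rescaling

`rescale_to_target` finds the single isotropic linear factor k such that
predicted mass of the inflated model plus armour equals a target:
closed-form k³ = ((target − armour)/a)^(1/b) / total for a positive
slope, bracketed bisection otherwise, with a 0.1% forward verification.
Scaling is uniform over all units — the expansion is a shape-preserving
inflation, with no differential per-unit scaling.

## Reporting conventions

Percentage ratios of volumetric means to the reference method (default
`CE2012_b`) are rounded half-away-from-zero to integer percent. Volume
tables are written at 4 decimals (m³), mass tables at 1 decimal (kg).
Table files contain no timestamps, so identical config + seed reproduce
them byte-for-byte; wall-clock timings appear only in the run log. The
packaged per-segment volume table is itself printed at 4 decimals, so
its pref/min/max columns sum to within a few 1e-4 of the published
totals while the ce column sums exactly; reports print recomputed sums
(e.g. the pref→ce volume increase recomputes to ~164%, not the published
165%), and where the literature reports both 3752 and 3751 kg for the
bivariate estimate the packaged table carries 3752.

## Synthetic data: what it emulates and what it does not

The skeleton generator emits sixteen box-built functional units laid out
as manifest + OBJ files, with axial units scaled per pose (default
multipliers 0.85 / 1.0 / 1.25 for min / pref / max) while limb meshes
are shared — reproducing the structural signature of a real multi-pose
reconstruction (axial dominance of the total, pose-invariant limb rows).
`single_axis` mode (default) stretches only the longitudinal dimension,
so unit volume scales linearly with the multiplier, emulating
intervertebral spacing; `isotropic` mode scales volume as the cube.
Box dimensions default to proportions where the trunk dominates
(~84% of the preferred total), comparable to a large quadrupedal
dinosaur. Closed-form volumes accompany every primitive: a·b·c for
boxes; for frusta the *polygonal* prismatoid volume (circular formula ×
n·sin(2π/n)/(2π)), since the hull of n-gon rings is polygonal and the
circular formula would overstate it; ellipsoid clouds record
(4/3)πabc as an upper bound their finite-sample hulls approach from
below, certified against the Monte-Carlo oracle rather than the
continuum formula.

Calibration sets draw log₁₀ volumes uniformly over [10⁻³, 10] m³ and
masses as 10^(log₁₀ a + b·log₁₀ V + ε), ε ~ N(0, σ²), defaulting to
a = 1200 kg·m⁻³ᵇ, b = 0.92, σ = 0.08, n = 20 — a mild negative allometry
with ~20% scatter, plausible for a quadrupedal-mammal hull-volume
calibration (the coefficient sits slightly above water density because
skeletons underfill their hulls). All generators are pure functions of
(spec, seed) and write ground-truth sidecars.

What the synthetic data does **not** emulate: anatomically realistic
geometry, mesh noise/holes from photogrammetry, articulated re-posing
(pose variation is a scaling surrogate), or armour shapes (armour is a
scalar mass). Passing tests therefore demonstrate correctness of the
geometry/statistics machinery and pipeline plumbing, not robustness to
scan pathology.

## Numerical choices and limitations

* Containment/convexity tolerances scale with the bounding-box diagonal
  (1e-8 relative); hull idempotence holds to 1e-12 relative, scaling and
  rigid-motion invariance to 1e-9.
* OBJ is written with 17 significant digits and round-trips coordinates
  to < 1e-9; PLY and STL store 32-bit floats (single-precision
  round-trip). STL merges duplicated vertices on load.
* Degenerate inputs fail loudly everywhere (coplanar units, non-positive
  masses/volumes/lengths, target mass below armour).
* Problem sizes in the test-suite simulations — 10 clouds × 10⁵
  Monte-Carlo samples, 200 recovery replicates, 1000 coverage
  simulations, 50 rescale round trips — were chosen as the smallest
  sizes at which the binomial/regression standard errors make the
  stated acceptance bands meaningful.
* No phylogenetic correction (PGLS), no compartment-wise density
  partitioning (lungs/air sacs), no concave alpha-shape variants (convex
  hulls only), no mesh repair or interactive visualisation.
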