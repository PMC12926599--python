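# Methods

This note documents the models behind `bhrobust`, the assumptions they make,
the parameters that matter, and what results on the synthetic phantom do and
do not say about real patients.

## Scope and intent

The package studies one question: how does imperfect reproducibility of the
breath-hold tumor position affect robustly optimized photon and proton lung
SBRT plans, and how much does the planning strategy (3D with setup shifts
only, 3D with enlarged shifts, 4D with multiple deformed planning images)
change that? Everything is built so the *comparison between strategies and
modalities* is meaningful; no component aims at clinical dosimetric accuracy.

## Synthetic thorax phantom

The phantom is a voxelized thorax built from analytic primitives on a regular
grid (default 3 mm isotropic; coarser grids are used in tests): an elliptical
body, two ellipsoidal lungs at −750 HU, an ellipsoidal heart and cylindrical
esophagus, aorta, vertebral column and spinal cord in the mediastinum, a
high-density (700 HU) chest-wall band around the lungs, and a spherical tumor
(CTV, 20 HU, default 25 mm diameter) inside one configurable lung. Mediastinal
organs take precedence over the lung masks, so the serial organs and the CTV
are pairwise disjoint. Optional seeded Gaussian HU texture is off by default,
keeping dose computations deterministic.

HU→stopping-power ratio (SPR) conversion is a piecewise-linear monotone curve
anchored at air (≈0.001) and water (1.0); photon attenuation uses relative
density (HU+1000)/1000. Both are generic literature-shaped curves — adequate
because only *relative* range/attenuation sensitivity matters here.

What the phantom does not emulate: realistic CT texture and artifacts,
lobulated tumors, diaphragm anatomy, truncated fields of view, or
inter-patient anatomical variety beyond jittered tumor size/position (the
multi-phantom mode draws diameter from 15–35 mm and perturbs the location
within the lung). Conclusions about absolute organ doses therefore do not
transfer to patients; orderings between strategies evaluated on identical
anatomy are the intended output.

## Breath-hold deformation model

A reproduced breath-hold is modeled as a rigid shift of the tumor inside an
otherwise static ribcage. The displacement field solves the Laplace equation
on the lung interior with Dirichlet data: the full shift on the tumor, zero
on and outside the lung boundary (hard Dirichlet at the wall; grid faces use
a mirror/Neumann closure, which is irrelevant for interior lungs and makes
the 1D slab case exactly linear). Because the equation is linear with the
same scalar boundary data on every component, every field is `shift × φ(x)`
for one harmonic potential φ solved once per phantom (sparse direct solve,
7-point stencil; residual tolerance 1e−3 mm).

Shifts are clamped so the tumor cannot cross the lung wall: every tumor voxel
is marched along the shift direction on the lung distance map, and the
magnitude is scaled so no voxel's wall clearance drops below
min(1.5 voxels, its initial clearance − 0.5 voxel), with a hard floor of one
voxel. The relative floor lets a wall-abutting tumor slide along or away from
the wall while forbidding motion into it.

Convention: the stored field is the forward displacement (tumor voxels carry
+shift). Warping an image into the deformed geometry resamples with the
lazily computed fixed-point inverse (early-stopped at a 1e−3 mm step, cap 20
iterations; composition residual is recorded and warned about above
0.25 × voxel). Accumulating a dose computed on the deformed geometry back to
the reference samples the dose at `x + u(x)` with the forward field — the
mathematically consistent direction under this convention. Displacement
resampling is restricted to the field's bounding box for speed; the field is
identically zero outside the lung, so this is exact.

Not modeled: independent rib/diaphragm motion, intra-breath-hold drift,
hysteresis, or any deformable registration of real image pairs.

## Error model and discrete scenario sets

Per-axis (LR, AP, CC) standard deviations, mm unless noted:

| source | Σ (systematic) | σ (random) |
|---|---|---|
| patient setup (PS) | 1.1, 1.5, 1.4 | 1.4, 1.7, 1.7 |
| breath-hold set A | 1.3, 1.2, 1.1 | 0.9, 1.0, 1.0 |
| breath-hold set B | 1.0, 1.2, 2.2 | 1.1, 1.6, 2.7 |
| SPR [%] | 3.8 | — |

Systematic errors persist for a whole course; random errors are redrawn per
fraction (setup) or per breath-hold (tumor position). Set A is used for
planning and a first evaluation; the larger set B only for evaluation.

The isotropic 90% radius of a combined error is `r = √(Σ²+σ²)·q` with
`q = √(χ²₃(0.90)) ≈ 2.5003` — the radius containing 90% of an isotropic 3D
Gaussian. With the per-axis maxima this yields 5.7 mm (PS), 4.1 mm (BH-A) and
7.0 mm (PS+BH-A in quadrature), the three radii used by the strategies.

Discrete sets: the 7-image planning set samples the zero shift plus ±r on
each axis; the 15-position setup set adds the 8 unit-cube vertex directions
(the minimal symmetric superset of the axis pattern reaching 15); the
105-shift evaluation grid crosses 15 systematic positions (at the Σ-only 90%
radius) with 7 per-breath-hold positions (at the σ-only radius), each
combination weighted by the product of the anisotropic per-axis Gaussian
densities, normalized to 1. The SPR perturbation set is a configured constant
(−4.7, 0, +4.7)% for protons and {0} for photons; the magnitude is not
derived from Σ_SPR inside this package.

## Analytic dose engines

Declared substitutions for clinical engines; they keep the correct
sensitivity structure (lateral shift, anatomy deformation, range error) at a
fraction of the cost. All beams are parallel and lie in the axial plane; dose
is computed in beam's-eye view (BEV: the volume rotated so the beam travels
along the +AP array axis) and rotated back. In parallel geometry a rigid
patient translation is exactly a lateral offset of the aperture/spot pattern
in BEV (the along-beam component is a no-op), which is how setup scenarios
are applied both in planning and evaluation.

**Photon**: depth dose `(1−exp(−d/10 mm))·exp(−0.0046 d)` of cumulative
radiological depth, normalized to its maximum; lateral transmission from an
error-function penumbra (σ = 3 mm) around a static aperture; each beam has
three concentric aperture segments (strategy margin −4/0/+4 mm) whose weights
the optimizer sets. Default 6 beams spread over the tumor-bearing hemithorax.

**Proton**: per energy layer an analytic Bragg curve — proximal plateau (0.4
of peak, distal fall-off σ 3 mm) plus a Gaussian peak (σ 5 mm, wide enough
not to alias on 5 mm grids) — evaluated at WEPL − nominal range; Gaussian
lateral spot profile (σ 5 mm) on the voxel lattice covering the target
projection plus the strategy margin; layers every 4 mm WEPL across the CTV
depth extent ± 6 mm, with NNLS-flattened layer weights forming a spread-out
peak; constant RBE 1.1. Default 3 beams. The SPR perturbation scales the
cached WEPL linearly (so photon doses are exactly invariant to it). Beams
with more than 10 layers split into two sub-beams of successive layers
(⌈n/2⌉/⌊n/2⌋, deepest first) — the breath-hold-sized delivery unit.

Spot/aperture placement margins equal setup radius + tumor-shift radius +
2 mm per strategy, mirroring how robust PBS plans set spot coverage from the
scenario magnitudes. Optional seeded multiplicative Gaussian dose noise
(default off) can mimic statistical engine noise.

## Robust optimization and normalization

Scenarios are the cross product of planning images × 15 setup shifts × SPR
members (15/45/105/315 per strategy). The optimizer minimizes a
softmax-smoothed worst case (temperature 2 Gy²) over scenarios of a composite
objective with nonnegative weights (L-BFGS-B, numeric gradients,
deterministic given the seed; the scaled-uniform start is kept if the
optimizer fails to improve it):

* CTV: mean squared deviation from the 54 Gy prescription over the scenario's
  (warped) CTV voxels — a uniform-dose objective; penalizing only a median
  statistic lets the optimizer tolerate cold target edges whose effect then
  compounds under fraction-wise error mixing,
* fall-off: quadratic penalty on dose exceeding `54·exp(−dist/10 mm)` on a
  sampled shell (≤ 800 voxels, 18 mm) around the CTV,
* chest wall: quadratic penalty above 30 Gy on a sampled chest-wall subset,
  weights 1 / 0.02 / 0.02 — set once on the default phantom and frozen.

Organs of interest are deliberately *not* objectives (their sparing comes
from the beam arrangement); they are only reported. Inside the optimizer
D50% is a Gaussian rank-smoothed soft median (exact for uniform dose); all
reporting uses the exact quantile. After optimization each plan is scaled so
the minimum robust-scenario CTV D50% equals 54 Gy — exact up to dose-grid
interpolation because dose is linear in the weights.

## Probabilistic evaluation

A simulated treatment draws: a systematic SPR member (protons, weighted by
the N(0, Σ_SPR) density at each member), systematic setup and breath-hold
shifts, then per fraction (3) a setup shift and per delivery unit a
breath-hold shift. Continuous draws map to the discrete cache grids by
nearest neighbor in per-axis Mahalanobis distance (ties to the lowest index);
the combined systematic+fraction setup shift maps to the 15-point grid, the
(systematic, per-BH) pair to the 105-image grid. Unit doses per (image,
setup, SPR) are computed on demand, accumulated to the reference anatomy
through the image's forward field, stored float32 in a bounded LRU cache and
reused; deformed images themselves are built lazily and shared across plans.

Nearest-neighbor mapping concentrates probability mass on the discrete
support (typical draws land on the pattern shell); this is the simplest
deterministic probability-consistent scheme and is validated by comparing
assignment frequencies to Monte-Carlo cell probabilities (rank correlation
on symmetry-orbit aggregates, since cells within an orbit have identical true
probability).

Metrics per treatment: CTV D50/D2/D98/D0% and HI = (D2%−D98%)/D50%;
ipsilateral lung V5Gy/V20Gy (absolute cm³); heart D0%/Dmean; esophagus,
aorta and spinal-cord D0%. `Dx%` is the interpolated descending order
statistic at rank `x·n/100 − 0.5` (so D0% is the voxel maximum; 100 voxels of
1..100 Gy give D50% = 50.5, D2% = 98.5). Summaries report Avg, SD, Med, IQR,
min, max and p90% — the 10th percentile for CTV dose levels, the 90th for HI
and organ metrics — with linear-interpolation percentiles; empty structures
yield NaN and are excluded.

Defaults: 10,000 treatments per plan per evaluation set. The test suite and
examples run 200 treatments per combination on a 5 mm grid, sizes chosen so
the full 6-plan × A/B pipeline completes in minutes on one CPU while leaving
the p90% orderings resolvable (their Monte-Carlo tolerance at n = 200 is
taken as 0.5 Gy).

## Known limitations

* Parallel beams: no divergence, no source-axis distance, so along-beam setup
  errors have no dosimetric effect.
* The heart and aorta sit partly lateral/proximal on this phantom; with the
  enlarged 4D spot margins their maximum-dose metrics can exceed the photon
  plans' even though the mean-dose and truly distal metrics (esophagus,
  spinal cord, lung volumes) remain clearly better for protons — the
  qualitative comparisons are therefore scoped to the latter.
* Per-spot weights are not individually optimized (segment/sub-beam level
  only); target homogeneity under extreme scenarios is correspondingly
  coarser than a clinical system would achieve.
* Discrete-scenario evaluation over-weights shell-magnitude errors relative
  to sampling the continuous distributions directly; both the planning and
  evaluation share this discretization, so comparisons remain consistent.
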