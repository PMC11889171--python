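# Methods

This note records the models, conventions and numerical choices behind
`fibdamage`, and what the synthetic benchmarks do and do not demonstrate.

## Geometry and depth

A lamella is modelled as a slab bounded by two milling surfaces, each
single-valued along the beam axis (a height field `h(u, v)` over the two
lateral voxel axes). Manual annotations — polylines on sparse slices,
roughly every 100 slices — are interpolated linearly along each polyline,
blended linearly between adjacent annotated slices, and extended unchanged
(nearest-slice clamping) beyond the first/last annotated slice. The height
field is triangulated by splitting each grid cell (default step 10 voxels)
along its main diagonal.

A particle's **depth** is the unsigned shortest 3-D distance to the nearer
triangulated sheet, not the vertical distance; **local thickness** is the
vertical separation of the two height fields. The nearest-point search is
exact with respect to the triangulation: because a sheet is a height
field, the vertical offset at the particle's own lateral position is an
upper bound on the true distance, and no surface point laterally farther
than that bound can be closer; grid cells are therefore visited in rings
of increasing lateral distance with early termination, and each candidate
cell's two triangles are tested with the standard closest-point-on-triangle
construction (compiled with numba). Tests verify agreement with a dense
brute-force surface sampling to machine precision at the raster limit.

Units: all geometry is computed in voxels (isotropic) and converted with
the table's pixel size (nm = voxels × Å/px / 10). The study regime this
package mirrors works on tomograms binned 8× (15.2 Å/px).

Particles laterally outside the annotated grids are flagged and excluded
from cohorts, with counts logged. Thickness summaries are taken over
per-tomogram mean thicknesses (sample SD; a single tomogram reports SD 0
with a flag). Whether lamella "thickness" means vertical or
surface-normal separation is not uniquely defined for tilted slabs;
vertical separation is used here.

## Cohorts and matched controls

Depth bins are half-open `[lower, upper)` intervals, 5 nm wide up to
60 nm; backside bins are half-open 1 µm intervals up to 5 µm, with the
per-particle backside distance equal to the acquisition area's distance to
the amorphous boundary plus the particle's signed lateral displacement
from the tomogram centre along the milling (x) axis. Negative distances
are flagged and excluded.

A matched control draws, per tomogram, as many particles as its source
cohort has there, from particles **deeper than an eligibility floor**. The
floor defaults to `max(bin upper edge, 60 nm)` — 60 nm being the deepest
studied bin — so controls lie outside the entire damage range; where that
empties a tomogram's pool the floor relaxes to the bin's upper edge
(logged), and a tomogram with no eligible particles at all has its cohort
particles dropped (logged). Where the pool is merely short, the control
takes what exists and the cohort is randomly downsampled to match, so
cohort and control stay equal per tomogram and in total. Equalization per
tomogram (rather than only in total) is a deliberate choice: the control's
purpose is to cancel per-tomogram confounders.

All draws come from a single seeded generator; every emitted assignment
records its seed.

## B-factors

For a cohort of `N` particles the subset series halves down to a minimum
of 400 particles (`N, N/2, N/4, …`); below two distinct sizes no line can
be anchored and the cohort is excluded (the study regime's 0–5 nm bin,
with only 25 particles, is the archetype). Three repeats independently
redraw every subset. All repeats' points enter one OLS fit of
`y = 1/resolution²` on `ln N`; per-size means ± SE are for plotting only.
Then `B = 2/slope` and `σ_B = 2σ_slope/slope²`.

On real data the per-subset resolutions come from external refinement
software and enter via a CSV series; the package's own FSC module
(integer-radius shells one Fourier voxel wide, DC excluded, no masking,
first downward 0.143 crossing by linear interpolation, Nyquist cap)
exists so the pipeline is self-contained on synthetic half-map fixtures.
Parity with a masked refinement-package FSC is not claimed.

## Damage curves and error propagation

Per depth bin, two statistics against the matched control:

- **B-factor ratio** `B_g/B_c`, SE in quadrature on the relative scale;
- **Δ extrapolated resolution** at 5000 particles:
  `y* = m·ln 5000 + c`, `resolution = 1/√y*`, with
  `σ_y = √((σ_m·x)² + σ_c²)` and `σ_res = σ_y/(2·y*^{3/2})`.
  The slope–intercept covariance is deliberately omitted from `σ_y`,
  reproducing the error model used in the upstream analysis this package
  mirrors; Monte-Carlo audits in the test suite quantify that the closed
  forms agree with sampling to within 3% in the regimes used.

Both curves, sampled at bin midpoints (7.5, 12.5, … nm), are fitted with
`y = A·e^(−kx) + c` by weighted least squares (weights `1/SE²`,
initialization from the first/last points, parameter tolerance 1e-10,
max 10,000 iterations). `R²` is reported unweighted, with a weighted
variant alongside. A fit with `k ≤ 0` or no convergence is flagged, never
silently accepted. Note that even when the B-ratio curve is exactly
exponential, the Δresolution curve is not (resolution is a square-root
transform of B), so its fitted rate is expected to sit slightly below the
generating rate — visible in both the worked example and the synthetic
benchmark.

The backside analysis reports the per-bin B extremes and the Spearman rank
trend (average ranks for ties; exact permutation p for ≤ 8 bins, else the
t-approximation). Reconstructing the trend from a *rounded* printed table
gives r = −0.31; the unrounded per-bin values, which are not published to
full precision, are required to reproduce a stronger printed value. The
amorphous-region length is the segmented area divided by its extent
perpendicular to the milling direction; group comparisons default to
Welch's t-test (the underlying study does not name its test; pooled-
variance and rank-sum variants are selectable).

## Synthetic generator

The generator emulates the study conditions: 167 tomograms of 490
particles (~82,000 total), lamella thickness 200 ± 30 nm, surfaces tilted
up to ±5° with 2 nm sinusoidal roughness, annotations sampled from the
true surfaces every 100 slices, tomograms of 512 × 512 × 386 voxels at
15.2 Å/px. Damage follows

    B(d) = B_bulk · (1 + (ΔB/B_bulk) · e^(−d/λ)),

with defaults B_bulk = 300 Å², ΔB = 1100 Å² (shallow-bin B ≈ 1400 Å²) and
λ = 5.4 nm (k = 0.185 nm⁻¹), echoing the regime of the reference tables.
This multiplicative exponential inflation is a modelling invention
consistent with the expectation that collision-cascade damage decays
exponentially; it is ground truth for recovery tests, not a mechanistic
claim. Subset "refinement" is emulated by a resolution oracle: a subset's
effective B is the mean ground-truth B(d) over its members, pushed through
`y = (2/B)·ln N + y₀ + ε` with Gaussian ε (SD 8 × 10⁻⁴ on the `y` scale,
chosen so fitted σ_B lands near the reference tables' printed SEs) and
`y₀ = 0`. Half-map fixtures share a Gaussian random signal plus per-half
noise with per-shell variance set so the expected FSC crosses 0.143 at a
designed frequency.

What the generator does **not** emulate: image formation (CTF, missing
wedge), particle ablation at the surfaces (its 0–5 nm bin is fully
populated, unlike real data), picking errors, or any backside damage
(backside bins are a null case by construction). Passing recovery
benchmarks therefore demonstrates the statistical machinery — geometry,
cohort construction, fitting, propagation — not robustness to those
real-data effects.

Every stochastic output is a pure function of (config, seed).

## Problem sizes and design choices

- The parameter-recovery benchmark runs ten study-scale bundles
  (~82,000 particles each) through the full pipeline and compares the
  median fitted ratio-curve rate with the generating 0.185 nm⁻¹; it
  completes in about a minute on one CPU.
- Reconstruction of the printed depth table is deterministic arithmetic;
  because the printed B-factors and resolutions are rounded, the refitted
  Δresolution decay rate lands at 0.166 nm⁻¹ (≈10% from the printed fit)
  while the B-ratio rate lands at 0.183 nm⁻¹.
- Pipeline stages are pure functions of (inputs, config, seed) and reports
  are byte-identical across reruns; no on-disk stage cache is kept —
  determinism plus fast stages make a digest cache state without benefit.
- Coordinates are treated as 0-based voxel positions at the file's stated
  binning; STAR columns are matched case-sensitively, both RELION-3.1
  named blocks and legacy bare blocks are accepted, and unknown columns
  round-trip opaquely. Annotations travel as plain CSV
  (`tomogram_id, sheet, slice_index, point_u, point_v`) — the container
  used by the original annotation tooling is not standardized, and CSV
  keeps fixtures language-neutral.

## Known limitations

- Depth is measured to the *interpolated* surface; annotation sparsity and
  surface roughness blur bin assignment by ~1–2 nm in the synthetic regime,
  which slightly flattens recovered decay curves (regression dilution).
- The FSC module is unmasked; its absolute resolutions differ from masked
  refinement-package values by construction.
- The exponential damage model conflates ablation and radiation damage in
  the shallowest bins; on real data those are distinct effects.
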