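# Methods

## Signal model

DENSE stores the tissue displacement `u` (mm) accumulated between tagging
and readout in the image phase. For encoding direction `e_i` (unit vector)
and encoding frequency `ke` (cycles/mm),

```
phi_i(v, t) = 2*pi * ke * (e_i . u(v, t))
```

The default scheme is the balanced four-point set — the four tetrahedral
unit vectors `(1,1,1)/sqrt(3)`, `(1,-1,-1)/sqrt(3)`, `(-1,1,-1)/sqrt(3)`,
`(-1,-1,1)/sqrt(3)` plus their negations from phase cycling, eight acquired
series — at `ke = 2.02` cycles/mm (0.495 mm/cycle sensitivity). The exact
direction set used by any given sequence is configurable
(`EncodingScheme.directions`); the tetrahedral ± set is the standard
balanced geometry and is our documented default assumption. Phase cycling's
role in stimulated-echo artifact suppression is not modelled; the ± pairs
simply enter the decode.

Decoding is voxelwise Moore–Penrose least squares,
`u = (1/(2*pi*ke)) * pinv(E) * phi`, using all eight measurements rather
than any matrix-subset inversion. For the balanced scheme the column sums
of `E` are zero, so a global phase offset common to all encodings produces
exactly zero displacement bias.

## Rigid bulk motion as a phase plane

A rigid translation `delta` during the mixing period adds the constant
`2*pi*ke*(e_i . delta)` to series `i`. A small rigid rotation `theta` about
a pivot displaces tissue at in-plane offset `(r_LR, r_AP)` from the pivot by
`(dAP, dLR) = theta*(r_LR, -r_AP)` (the rotation field linearized at the
pivot), which encodes to a first-order phase in the image coordinates. Any
combination is therefore a plane `a*x + b*y + c` per (frame, encoding)
image. The linearization is enforced: simulated rotations beyond 5 degrees
raise an error; at the amplitudes of interest (fractions of a degree) the
quadratic term is negligible relative to the encoded tissue phase.

The correction assumes the outermost one-voxel ring of the combined
hemisphere mask is free of cardiac-driven displacement (the skull constrains
the periphery; pulsatile deformation concentrates interiorly), so ring phase
estimates the bulk plane. `interior_peripheral_compare` exposes that
assumption as a computable contrast between eroded-interior and peripheral
peak-to-peak summaries.

## Pipelines

Stage order, Standard: background removal (multiply each frame by the
complex conjugate of frame 0 of its series) → phase extraction → per-voxel
1-D temporal unwrap → linear interpolation of the 10 acquired frames onto a
19-frame grid → retrospective trim → voxelwise linear detrend over time →
reference to frame 0 → least-squares decode.

Timing conventions. Frame `k` of `n` is placed at `k * coverage * RR / n`
(spacing = the protocol's temporal resolution, `coverage` = 1.10 by
default); the interpolated grid uses the same convention with `n = 19`
(linear interpolation, with linear extrapolation for the single tail frame
beyond the last acquired time). The trim keeps frames with nominal time
`<= `the measured mean RR (closed bound): with the measured RR equal to the
prescription, 18 of 19 frames survive. Whether the original procedure
trimmed the 10 acquired or the 19 interpolated frames is ambiguous; the
printed stage order (interpolate, then trim) is followed.

Detrending subtracts the full per-voxel OLS line (slope and intercept);
referencing then re-zeros frame 0, making the intercept choice irrelevant.
With fewer than 3 frames the detrend is skipped with a warning.

Linear Fit inserts an OLS plane fit to the ring phase, subtracted in the
real domain from every voxel of each (frame, encoding) image, after
detrending/referencing and just before decoding. Complex Fit inserts the
wrap-aware fit immediately after the temporal unwrap and before
interpolation (interpolation smears residual wraps, after which
complex-domain subtraction can no longer remove them); the subtraction is
performed on the unit circle, `phi' = angle(exp(i*phi) * exp(-i*plane))`,
so integer-2*pi ledges vanish identically.

One design addition: complex-domain subtraction necessarily returns phase
wrapped into (-pi, pi], while the legitimate tissue phase can exceed pi
(0.15 mm along an encoding direction is about 3.3 rad at the default `ke`).
The Complex Fit pipeline therefore re-runs the 1-D temporal unwrap after the
subtraction. Without this step the pipeline could not return the true phase
whenever tissue phase wraps; with it, noiseless recovery is exact.

## Wrap-aware plane fitting

Objective: `J(a,b,c) = sum_ring (1 - cos(phi - a*x - b*y - c))`, which is
invariant to 2*pi offsets and equals half the squared residual to second
order. (A squared-wrapped-difference variant is available behind
`objective="squared"`.) Coordinates are voxel indices centered at the
combined-mask centroid, decorrelating slopes from intercept.

Stage 1 is a coarse grid: slopes over `[-pi/R, pi/R]` per axis (R = half the
mask extent on that axis, so any plane with an across-mask excursion up to
2*pi per axis is inside the grid) at 21 steps, intercept over `(-pi, pi]`
at 16 steps. The grid resolves the objective's basins (basin width ~pi/R in
slope, grid step pi/(10R)). Stage 2 refines the best grid point with
Nelder–Mead (tolerance 1e-8 on J), then polishes with iterated linear least
squares on the wrapped residual — a Gauss–Newton step that is exact in the
locally quadratic regime and drives noiseless fits to machine precision.
The returned objective is never worse than the best grid point; a
`converged` flag records optimizer status.

The identifiable slope range bounds the correctable rotation: at 4 mm
voxels and `ke = 2.02`, an in-plane rotation `theta` produces slopes of
about `29.3 * theta` rad/voxel (per tetrahedral component), so the default
grid covers rotations up to roughly 0.2 degrees per frame on the default
60-voxel mask. The phantom's default induced rotations (<= 0.15
degrees/frame) sit inside that range while still driving the phase through
multiple wraps across the object — the artifact class the complex-domain
correction exists for. Larger rotations would need a wider grid
(`n_slope`/range are arguments) at the cost of a denser search.

## The phantom

Geometry: two elliptical hemispheres (half-ellipses of a 0.9-fraction
bounding ellipse on the default 60 x 60 grid at 4 mm in-plane) separated by
a one-voxel midline gap; tissue magnitude 1. Displacement
`u(v,t) = a(v) * s(t) * p`:

- `a(v)` is a raised cosine of the normalized Euclidean depth
  `(d - 1)/(d_max - 1)`: exactly zero on the outer ring (depth 1), exactly
  1 at the deepest voxel. Interior > periphery is the only constraint the
  real anatomy imposes; the raised cosine is a smooth, analytic choice.
- `s(t) = sin^2(pi * t / t_last)` over the sampled span, with the endpoints
  forced to exactly zero and the sampled maximum normalized to exactly 1 —
  so the cycle starts and ends at rest and the configured per-axis peaks
  `p` (defaults 0.10, 0.04, 0.12 mm for A/P, L/R, S/I, near the reported
  magnitudes of cardiac brain pulsation) are attained exactly. The peak
  voxelwise peak-to-peak is then `||p||` analytically.
- Per-axis peaks must stay below `1/(2*ke)` unless `allow_wraps=True`.

Bulk motion: per-frame translations and in-plane rotations (frame 0 is the
zero-motion reference), with the closed-form plane coefficients stored in
`PhantomTruth.bulk_planes`. Default amplitudes for "induced motion"
experiments are <= 0.3 mm and <= 0.15 degrees per frame: large enough to
produce constant offsets, temporal-unwrap aliasing and spatial wrap ledges,
small enough that the plane slopes stay in the fitter's identifiable range.
Phase is wrapped before complex Gaussian noise is added on the real and
imaginary channels (the physical order: a scanner yields wrapped, noisy
phase). `noise_sd` is relative to tissue magnitude 1; 0.05 corresponds to
SNR 20. All randomness flows from the single config seed.

What the phantom does **not** emulate: spiral k-space sampling and
reconstruction, coil sensitivities, stimulated-echo amplitude decay and T1
relaxation, through-plane motion gradients, respiration, and physiologic
variability of the pulse shape. Passing phantom tests therefore validates
the *processing chain* — encoding algebra, unwrapping, timing arithmetic,
plane estimation and subtraction, statistics — not the acquisition physics,
and real-data performance additionally depends on SNR, segmentation quality
and deviations from the stationary-ring assumption.

## Ground truth under temporal normalization

The pipeline's detrend removes any constant-velocity drift per voxel; the
sampled phantom pulse has a small but nonzero OLS slope on the trimmed
frame grid, so the raw analytic truth is not what an ideal pipeline should
return. `PhantomTruth.expected_field` therefore maps the analytic truth
through the same (exactly linear) interpolate–trim–detrend–reference
operations; comparisons against it isolate phase-domain errors. On clean
data the Standard pipeline matches it to machine precision, which is the
package's end-to-end identity check.

## Statistics

Pair regression is OLS of map 2 on map 1 (the direction is part of the
contract and tested); `R^2 = 1 - SS_res/SS_tot`; RMSD is between the raw
paired values, not regression residuals. Spearman uses average ranks.
The Wilcoxon signed-rank test is two-sided, exact for up to 25 nonzero
differences and normal-approximated with continuity correction beyond;
Bonferroni multiplies by the number of comparisons (default 3, one per
imaged slice) and caps at 1. The effect size is `r = |Z|/sqrt(N)` with `Z`
recovered from the two-sided p-value. RMSSD is the root mean square of
successive RR differences; for i.i.d. RR jitter of SD sigma it converges to
`sigma*sqrt(2)`.

Percent change is reported in two modes because both appear in practice:
`simple = 100*(new-old)/old` and `symmetric = 100*|new-old|/midpoint` (the
only definition under which a decrease can exceed 100%). Audit outputs name
the mode used.

## Numerical choices and conventions

- Wrapping convention `(-pi, pi]`, matching `numpy.angle`; the temporal
  unwrap is `numpy.unwrap` (the minimal-change recurrence). A true
  inter-frame change beyond pi aliases — documented failure mode, with a
  constructed counterexample in the tests.
- Zero-magnitude voxels carry zero phase and are excluded from masks.
- Ring extraction erodes with a 4-connectivity cross (closed one-voxel ring
  on convex masks); 8-connectivity is an option. Hemisphere masks are
  combined by union before ring extraction, so the midline gap contributes
  interior ring voxels, deliberately.
- Hemisphere segmentation: Otsu threshold (or explicit), components >= 5%
  of the largest kept (the hemispheres are two separate components; keeping
  only the largest would discard one), split at the midline column.
  Externally supplied masks bypass segmentation.
- Top-5% "maximum" p2p uses the ceiling count; a floor variant is a flag.
- Peak-to-peak is exhaustive over frame pairs (<= 171 pairs at 19 frames).
- Whether published Spearman/R² values were computed on voxelwise p2p maps
  or stacked per-frame magnitudes is not determinable; this package
  defaults to p2p maps and accepts any scalar map pair.
- Fit coordinates are voxels, not mm, centered at the mask centroid — an
  assumption; only the subtracted plane values matter, which are
  origin-independent.

## Problem sizes

Default analyses use the 60 x 60-voxel phantom, 10 acquired frames and 8
encodings (80 wrapped-plane fits per corrected scan, each a 21 x 21 x 16
grid plus refinement over a ~150-voxel ring), 1000 null simulations for the
Wilcoxon calibration and 10^4 beats for the RMSSD check. The full test
suite and the acceptance script each run in well under a minute on one CPU.

## Known limitations

- The stationary-ring assumption removes *any* ring-coherent planar phase,
  including genuinely cardiac bulk motion of the whole head; on real data
  this can suppress part of the signal of interest (the corrected baseline
  displacement is expected to drop, as reported for the in-vivo case).
- One plane per 2-D slice: through-plane rotation gradients within the
  slice are not separable at fixed z.
- 1-D temporal unwrapping cannot recover true inter-frame tissue changes
  beyond pi; the Complex Fit path is robust to *bulk-induced* aliasing but
  not to arbitrarily fast tissue motion.
- The identifiable rotation range is bounded by the fitter's grid (see
  above); extreme motion needs a wider, denser search.
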