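# densebrain

Displacement mapping for cardiac-gated **DENSE** (Displacement ENcoding with
Stimulated Echoes) brain MRI, with rigid bulk-motion correction based on the
outer ring of brain tissue.

## The problem

With every heartbeat the brain tissue pulses by a few hundredths of a
millimetre. DENSE measures this directly: displacement `u` accumulated
during the mixing period appears as image phase

```
phi_i = 2*pi * ke * (e_i . u)
```

for encoding direction `e_i` and encoding frequency `ke` (cycles/mm; the
default 2.02 cycles/mm gives a 0.495 mm/cycle sensitivity). A balanced
four-point scheme with phase cycling acquires eight directions, and the
per-voxel displacement vector is recovered by least squares through the
encoding matrix.

That sensitivity is also the method's weakness: sub-millimetre rigid head
motion corrupts the maps. A rigid translation adds a constant phase per
image; a small rigid rotation adds a spatially first-order phase — so any
rigid motion appears as a phase **plane** `a*x + b*y + c`. Because the skull
holds the brain's periphery nearly still, the phase observed on the
one-voxel **outer ring** of the hemisphere mask estimates that plane, which
can then be subtracted from the whole image, frame by frame.

`densebrain` implements three post-processing pipelines:

- **Standard** — background-phase removal (complex conjugate of frame 0),
  per-voxel 1-D temporal phase unwrapping, linear interpolation of the 10
  acquired frames to 19, retrospective trimming of frames beyond the
  measured mean RR interval (from the PPG trace), voxelwise linear
  detrending, referencing to frame 0, and least-squares decoding.
- **Linear Fit** — Standard, plus an OLS plane fit to the ring phase
  subtracted in the real domain at the end of the chain.
- **Complex Fit** — Standard, plus a *wrap-aware* plane fit (coarse grid
  search over the wrap-invariant objective `J = sum(1 - cos(phi - plane))`,
  then simplex refinement) subtracted **in the complex domain** right after
  unwrapping, where integer-2*pi ledges vanish identically.

A synthetic phantom (two elliptical hemispheres, cardiac displacement pulse
that vanishes on the ring, closed-form bulk-motion phase planes, wrapping,
complex Gaussian noise) provides analytic ground truth for every stage, and
a metrics module supplies the scan-pair and test–retest statistics
(R², RMSD, Spearman's rho, Wilcoxon signed-rank with Bonferroni correction,
RMSSD heart-rate variability) plus the protocol-timing arithmetic.

## Worked example

```python
import numpy as np
from densebrain import (BulkMotionParams, EncodingScheme, PhantomConfig,
                        generate_phantom, run_pipeline, simulate_acquisition)

config = PhantomConfig(noise_sd=0.05, seed=7)      # 5% complex noise
scheme = EncodingScheme()                          # ke = 2.02 cycles/mm
_, masks, truth = generate_phantom(config)
bulk = BulkMotionParams.random(config.n_frames, max_translation_mm=0.3,
                               max_rotation_deg=0.15, seed=8)
series = simulate_acquisition(truth, bulk, scheme, config)

expected = truth.expected_field()                  # analytic ground truth
m = truth.combined_mask()
for mode in ("standard", "linear_fit", "complex_fit"):
    result = run_pipeline(series, masks=masks, mode=mode)
    rmse = np.sqrt(np.mean((result.field.data[:, :, m]
                            - expected.data[:, :, m]) ** 2))
    print(f"{mode:12s} RMSE vs truth: {rmse:.5f} mm")
```

prints

```
standard     RMSE vs truth: 0.11000 mm
linear_fit   RMSE vs truth: 0.07626 mm
complex_fit  RMSE vs truth: 0.00273 mm
```

The uncorrected error (0.11 mm — on the order of the cardiac motion itself)
is decoded bulk-motion phase. The real-domain correction removes most of it
but is degraded by residual 2*pi wrap ledges; the complex-domain correction
reaches the noise floor. On noiseless data the Complex Fit recovery is
exact to machine precision.

The `examples/` directory has one short script per capability (protocol
timing, end-to-end phantom recovery, motion correction, wrap robustness,
reproducibility metrics); each prints the numbers it computes and what they
mean. A thin CLI wraps the same calls:

```sh
densebrain timing --bpm 50
densebrain simulate --out sim --seed 7 --noise-sd 0.05 --max-rotation 0.1
densebrain process --input sim --out maps --pipeline complex
```

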