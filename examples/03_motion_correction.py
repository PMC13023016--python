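"""Bulk-motion corruption and outer-ring correction, all three pipelines.

Adds random per-frame rigid motion (translations up to 0.3 mm, in-plane
rotations up to 0.15 degrees) to the phantom acquisition.  Each rigid
motion contributes a planar phase per image; the Linear Fit and Complex Fit
pipelines estimate that plane from the stationary outer ring of brain
tissue and subtract it.
"""

import numpy as np

from densebrain import (
    BulkMotionParams,
    EncodingScheme,
    PhantomConfig,
    generate_phantom,
    run_pipeline,
    simulate_acquisition,
)

config = PhantomConfig(noise_sd=0.05, seed=7)  # 5% complex noise
scheme = EncodingScheme()
_, masks, truth = generate_phantom(config)
bulk = BulkMotionParams.random(
    config.n_frames, max_translation_mm=0.3, max_rotation_deg=0.15, seed=8
)
series = simulate_acquisition(truth, bulk, scheme, config)

expected = truth.expected_field()
m = truth.combined_mask()
for mode in ("standard", "linear_fit", "complex_fit"):
    result = run_pipeline(series, masks=masks, mode=mode)
    diff = result.field.data[:, :, m] - expected.data[:, :, m]
    rmse = np.sqrt(np.mean(diff**2))
    print(f"{mode:12s} RMSE vs truth: {rmse:.5f} mm")

print()
print("The uncorrected (standard) error is dominated by the decoded bulk")
print("phase planes.  Linear Fit removes most of the contamination but is")
print("degraded wherever the temporal unwrap aliased; Complex Fit reaches")
print("the noise floor.  Per-image plane coefficients are in result.fits.")
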