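"""Why the complex-domain subtraction matters: residual phase wraps.

A 0.2-degree in-plane rotation at 4 mm voxels tilts the phase by more than
a full cycle across the brain, so the acquired phase wraps spatially and
the per-voxel temporal unwrap aliases by 2*pi in parts of the image.  The
Linear Fit pipeline (real-domain subtraction) cannot remove those integer-
cycle ledges; the Complex Fit pipeline subtracts the fitted plane on the
unit circle, where 2*pi offsets vanish identically.
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
from densebrain.encoding import encode_series

config = PhantomConfig()
scheme = EncodingScheme()
_, masks, truth = generate_phantom(config)
rot = np.array([0.0, 0.2, -0.2, 0.2, 0.0, -0.2, 0.2, -0.2, 0.2, -0.2])
bulk = BulkMotionParams(np.zeros((10, 3)), rot)
series = simulate_acquisition(truth, bulk, scheme, config)

coeff = truth.bulk_planes[1, 0]
rx, ry = truth.ring.half_extents()
excursion = abs(coeff[0]) * 2 * rx + abs(coeff[1]) * 2 * ry
print(f"bulk phase excursion across the ring: {excursion:.1f} rad "
      f"({excursion / (2 * np.pi):.1f} wraps)")

expected_phase = encode_series(truth.expected_field().data, scheme)
m = truth.combined_mask()
for mode in ("linear_fit", "complex_fit"):
    result = run_pipeline(series, masks=masks, mode=mode)
    err = np.abs(result.phase.data[:, :, m] - expected_phase[:, :, m])
    print(f"{mode:12s} max |phase error|: {err.max():.3g} rad")

print()
print("Linear Fit leaves errors of about 2*pi (residual wrap ledges in the")
print("displacement maps); Complex Fit removes the same plane exactly.")
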