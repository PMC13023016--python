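"""Simulate a motion-free phantom scan and recover its displacement field.

Builds the two-hemisphere phantom with a cardiac displacement pulse
(interior tissue moves, the outer ring is stationary), encodes it with the
balanced four-point scheme, runs the Standard Pipeline, and compares the
decoded field against the analytic ground truth.
"""

import numpy as np

from densebrain import (
    EncodingScheme,
    PhantomConfig,
    generate_phantom,
    mean_displacement_curves,
    peak_to_peak_map,
    run_pipeline,
    simulate_acquisition,
    summarize_p2p,
)

config = PhantomConfig()  # 60x60 voxels at 4 mm, 10 frames, noiseless
scheme = EncodingScheme()  # ke = 2.02 cycles/mm -> 0.495 mm/cycle
_, masks, truth = generate_phantom(config)
series = simulate_acquisition(truth, None, scheme, config)

result = run_pipeline(series, masks=masks, mode="standard")
expected = truth.expected_field()
m = truth.combined_mask()
rmse = np.sqrt(np.mean((result.field.data[:, :, m] - expected.data[:, :, m]) ** 2))

p2p = peak_to_peak_map(result.field)
mean_p2p, max_p2p = summarize_p2p(p2p, masks)
curves = mean_displacement_curves(result.field, masks)

print(f"frames decoded:        {result.field.n_frames} "
      f"(10 acquired -> 19 interpolated -> trimmed at the measured RR)")
print(f"RMSE vs ground truth:  {rmse:.2e} mm")
print(f"mean p2p displacement: {mean_p2p:.4f} mm")
print(f"max (top-5%) p2p:      {max_p2p:.4f} mm")
print(f"peak A/P curve value:  {curves[:, 0].max():.4f} mm")
print()
print("The RMSE at machine precision shows the full chain -- background")
print("removal, temporal unwrapping, interpolation, trimming, detrending,")
print("referencing and least-squares decoding -- is exact on clean data.")
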