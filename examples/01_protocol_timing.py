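"""Protocol timing arithmetic for a cardiac-gated DENSE brain scan.

The echo spacing is chosen at prescription time so that the 10-echo
stimulated-echo train covers 110% of the cardiac cycle; one preparation is
played every 2 RR intervals for each of 8 encoding directions and 4
averages.  This prints the temporal resolution, scan duration and image
count across the plausible heart-rate range.
"""

from densebrain import ProtocolParams, protocol_timing

for bpm in (50, 70, 90):
    t = protocol_timing(ProtocolParams(heart_rate_bpm=bpm))
    print(
        f"{bpm:3d} bpm: temporal resolution {t.temporal_resolution_ms:6.2f} ms, "
        f"scan duration {t.scan_duration_s:5.2f} s, "
        f"{t.total_images} images"
    )

print()
print("Slower hearts give coarser temporal resolution but identical image")
print("counts; scan duration scales directly with the RR interval.")
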