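"""Collective-migration metrics on synthetic PIV-like inputs.

Generates a velocity-field sequence with a known 50-um lateral correlation
length (30-min cadence over ~14 h, as in a scratch-wound imaging protocol),
recovers the length from the binned correlation function C(r), summarizes
the movement-angle distribution, and measures leading-edge speed from an
advancing fluorescence-front mask stack with per-row jitter.
"""

import numpy as np

from rcn.fixtures import synthetic_front_masks, synthetic_velocity_fields
from rcn.motility import (correlation_length, correlation_profile,
                          leading_edge_speed, movement_angle_map)

fields = synthetic_velocity_fields(length_um=50.0, v_mean_um_min=0.3,
                                   n_frames=28, seed=7)
profiles = [correlation_profile(f) for f in fields]
est = correlation_length(profiles, exclusion_min=60.0)
print(f"Imposed lateral correlation length: 50 um; recovered: {est:.1f} um "
      f"(averaged over {sum(p.time_min >= 60 for p in profiles)} frames, "
      "first hour excluded).")

# per-vector directional jitter (uncorrelated) for the angle statistics
jittered = synthetic_velocity_fields(length_um=50.0, v_mean_um_min=0.3,
                                     angle_sd_deg=20.0, n_frames=28, seed=8)
amap = movement_angle_map(jittered)
mean_row = amap.mean(axis=0)
fwd = float(mean_row.loc[-15.0:15.0].sum())
print(f"Movement angles: {100 * fwd:.0f}% of PIV vectors within 15 deg of "
      "the wound-closure direction (20-deg directional jitter plus lateral "
      "fluctuations imposed).")

stack = synthetic_front_masks(speed_um_h=20.0, noise_px=2.0, n_frames=28,
                              shape=(64, 400), seed=7)
speed, fallback = leading_edge_speed(stack.masks, stack.frame_interval_min,
                                     stack.pixel_size_um)
print(f"Leading-edge speed: imposed 20 um/h, recovered {speed:.2f} um/h"
      f"{' (slope estimate; front did not span the field of view)' if fallback else ''}.")
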