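"""Acceptor photobleaching: donor dequenching quantified by linescan.

Destroying the acceptor abolishes FRET, so the donor brightens wherever
transfer occurred: recovery% = (1 − pre/post)·100.  With complete bleaching
the per-pixel recovery equals 100·E, the true FRET fraction.
"""

import numpy as np

from fretscope import (SceneConfig, build_mask, generate_apb_pair,
                       peripheral_recovery_summary, radial_recovery_profile)

base = dict(image_shape=(64, 64), cell_radius_px=22, n_frames=1,
            boundary_motility_amp_px=0.0, gauss_noise_sd=0.0,
            poisson_like=False, pulse_shape="constant", seed=3,
            baseline_activity=0.0, hotspot_activity=0.3,
            hotspot_angular_width_deg=360.0, hotspot_edge_depth_px=4.0)

profiles = []
for bleach, label in [(0.2, "2X"), (0.5, "5X"), (1.0, "10X")]:
    pair = generate_apb_pair(SceneConfig(**base), bleach, dose_label=label)
    mask = build_mask(pair.pre.acceptor)
    profiles.append(radial_recovery_profile(pair, mask))

prof = profiles[-1]
print("distance from edge (px) vs donor recovery (%) at full bleach:")
for d, r in list(zip(prof.distance_bin_centers, prof.mean_recovery_pct))[:8]:
    print(f"  {d:5.1f} px   {r:6.2f} %")
print("→ recovery is confined to the 4-px membrane band where the sensor "
      "is active (30% = the true FRET fraction there).")

table = peripheral_recovery_summary(profiles, band_px=4.0)
print("\nperipheral recovery vs light dose:")
print(table.to_string(index=False))
print("→ recovery rises with bleach dose, saturating toward 100·E.")
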