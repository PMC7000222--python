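"""Cell-shape dynamics and the coupling of membrane motility to activity.

Mean fractional area/perimeter change summarizes shape turnover; the
boundary-velocity map measures protrusion/retraction speed along the edge;
binning near-membrane activity against motility reveals whether active
zones move more or less than quiet ones.
"""

import numpy as np

from fretscope import (SceneConfig, boundary_velocity_map, build_mask,
                       compute_fret_index, fractional_changes, generate_scene,
                       motility_fret_correlation, near_membrane_signal)

cfg = SceneConfig(seed=11, n_frames=30, boundary_motility_amp_px=1.2,
                  motility_activity_coupling=-0.9,   # activity quiets the edge
                  gauss_noise_sd=0.5, detector_gain=0.5)
frames, _ = generate_scene(cfg)
fret_t = compute_fret_index(frames)
mask = build_mask(frames.acceptor)

morpho = fractional_changes(mask)
print(f"mean fractional area change     = "
      f"{morpho.mean_fractional_area_change:.4f}")
print(f"mean fractional perimeter change = "
      f"{morpho.mean_fractional_perimeter_change:.4f}")
print("→ per-frame shape turnover normalized to the first frame.")

mmap = boundary_velocity_map(mask, frames.frame_interval_min)
print(f"median |edge velocity| = "
      f"{np.median(mmap.motility_um_per_min):.3f} µm/min")

mmap.near_membrane_signal = near_membrane_signal(
    fret_t, mask, n_frames=mask.n_frames - 1)
corr = motility_fret_correlation(mmap)
print(f"Spearman rho (binned activity vs motility) = "
      f"{corr.spearman_rho:+.3f}")
print("→ negative: the membrane moves less where the kinase is active, "
      "reproducing the planted anticorrelation.")
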