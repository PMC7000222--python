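"""Spatial compartmentalization and temporal pulses of biosensor activity.

Quadrant mean traces locate the high-FRET quadrant (HFQ); the periodogram
of the quadratically detrended HFQ trace yields the dominant pulse period.
"""

import numpy as np

from fretscope import (SceneConfig, build_mask, compartment_summary,
                       compute_fret_index, dominant_period, generate_scene,
                       quadrant_labels, quadrant_mean_traces,
                       sector_kymograph)

cfg = SceneConfig(seed=21, n_frames=50)   # 25-min movie, 3.5-min pulses
frames, _ = generate_scene(cfg)
fret_t = compute_fret_index(frames)
mask = build_mask(frames.acceptor)
traces = quadrant_mean_traces(fret_t, quadrant_labels(mask),
                              frames.frame_interval_min)

s = compartment_summary(traces)
print(f"HFQ = {s.hfq_id}: peak mean FRET_T {s.max_fret_hfq:.2f} au at "
      f"t = {s.t_at_max:.1f} min; LFQ ({s.lfq_id}) reads "
      f"{s.lfq_at_same_time:.2f} au at the same instant")
print("→ activity is spatially compartmentalized: one quadrant dominates.")

hfq = int(s.hfq_id[1]) - 1
psd = dominant_period(traces.mean_intensity[hfq], frames.frame_interval_min)
print(f"dominant period = {psd.dominant_period_min:.2f} min "
      f"(configured pulse period {cfg.pulse_period_min} min; the estimate "
      "sits on the nearest periodogram grid frequency)")

kymo = sector_kymograph(fret_t, mask,
                        frame_interval_min=frames.frame_interval_min)
row = np.nanmean(kymo.mean_intensity, axis=1)
peak_depth = kymo.distance_bins_px[np.nanargmax(row)]
print(f"sector kymograph ({kymo.arc_length_px}-px arc): time-averaged "
      f"activity peaks {peak_depth:.1f} px from the membrane")
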