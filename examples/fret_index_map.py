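"""Bleed-through correction: from raw channels to a FRET-index map.

FRET_T = I_FRET − α_D·I_Donor − α_A·I_Acceptor removes donor emission
leaking into the acceptor band (α_D) and directly excited acceptor (α_A).
On a zero-noise synthetic scene the corrected map equals the true
sensitized emission to machine precision.
"""

import numpy as np

from fretscope import (BleedThroughCoefficients, SceneConfig,
                       compute_fret_index, estimate_bleedthrough,
                       generate_scene)
from fretscope.synthetic import noise_free

cfg = noise_free(SceneConfig(seed=7))
frames, truth = generate_scene(cfg)

coeffs = BleedThroughCoefficients(alpha_d=0.55, alpha_a=0.028)
fret_t = compute_fret_index(frames, coeffs, median_filter=False)

err = np.max(np.abs(fret_t - truth.sensitized_truth))
print(f"max |FRET_T - truth| = {err:.2e} au  (exact inversion, no noise)")

# calibrate the slopes from a donor-only scene instead of assuming them
donor_only = noise_free(SceneConfig(seed=8, acceptor_expression=0.0,
                                    baseline_activity=0.0,
                                    hotspot_activity=0.0))
d_frames, _ = generate_scene(donor_only)
alpha_d = estimate_bleedthrough(d_frames, "donor")
print(f"calibrated alpha_D = {alpha_d:.4f}  (configured 0.55: the slope of "
      "Dex-Aem vs Dex-Dem in a donor-only cell)")
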