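# fretscope

Quantitative analysis of **intermolecular FRET biosensor imaging** — the
kind of experiment in which a donor-labelled kinase and an
acceptor-labelled conformation-specific binder report enzyme activation as
sensitized acceptor emission in living cells.  The package covers the full
desk side of such a study: bleed-through-corrected FRET-index maps,
acceptor-photobleaching (APB) recovery linescans, quadrant
compartmentalization statistics, pulse-period spectral analysis, sector
kymographs, cell morphodynamics, membrane-motility/activity coupling, and
one-site binding fits — together with a seeded synthetic-scene generator
whose ground truth validates every stage.

It is written for cell-biology and biophysics groups who have three-channel
confocal time-lapse stacks (donor excitation/donor emission `Dex-Dem`,
donor excitation/acceptor emission `Dex-Aem`, acceptor
excitation/acceptor emission `Aex-Aem`) and want reproducible, scriptable
quantification instead of one-off spreadsheet analysis.

## The quantities it computes

**FRET index (FRET_T).** The sensitized-emission channel is corrected for
spectral crosstalk:

```
FRET_T = I_FRET − α_D · I_Donor − α_A · I_Acceptor
```

with `α_D` the slope of donor bleed-through into the acceptor band and
`α_A` the slope of direct acceptor cross-excitation, both measured on
single-label samples (defaults 0.55 and 0.028), optionally followed by a
2×2 median filter and 8-bit export.

**Acceptor photobleaching.** Donor dequenching after bleaching quantifies
FRET independently:

```
recovery% = (1 − I_pre / I_post) · 100
```

resolved versus distance from the cell edge by a linescan from every
boundary pixel to the centroid.  With complete bleaching the per-pixel
recovery equals `100·E`, the true FRET fraction.

**Spatio-temporal statistics.** Per-frame masks (Otsu or fixed threshold,
hole filling, particle removal) are split into four quadrants through the
centroid; quadrant mean traces `Σ pixel / n` identify the high- and
low-FRET quadrants (HFQ/LFQ).  The dominant pulse period is the maximum of
the periodogram of the quadratically detrended trace.  Sector kymographs
show activity versus time and distance from the membrane within a 40-px
arc.  Morphodynamics are summarized as `Σ|ΔA_i|/A_1/(n−1)` (and the
perimeter analogue); a signed-distance boundary-velocity map pairs edge
motility one-to-one with near-membrane activity, binned in 3-intensity-unit
bins with a cubic fit `f = y0 + a·x + b·x² + c·x³`.

**Binding.** Apparent dissociation constants from the monovalent isotherm
`Y = Bmax·X/(K_D + X)` by nonlinear least squares.

## A worked example

`examples/activity_pulses.py` generates a 25-min synthetic movie (2
frames/min) with a membrane-proximal hotspot pulsing every 3.5 min, then
runs segmentation → FRET index → quadrant analysis → periodogram:

```
HFQ = Q4: peak mean FRET_T 16.76 au at t = 4.5 min; LFQ (Q3) reads 4.69 au at the same instant
→ activity is spatially compartmentalized: one quadrant dominates.
dominant period = 3.57 min (configured pulse period 3.5 min; the estimate sits on the nearest periodogram grid frequency)
sector kymograph (40-px arc): time-averaged activity peaks 0.5 px from the membrane
```

The hotspot was planted at +45° (bottom-right, Q4) within 8 px of the
membrane, so each number checks out against the generator's ground truth:
the dominant period lands on the periodogram grid frequency nearest
1/3.5 min⁻¹, and the kymograph localizes activity to the membrane band.
The other scripts in `examples/` walk through scene simulation,
bleed-through calibration, photobleaching linescans, morphodynamics/motility
coupling, and K_D fitting the same way.

There is also a thin CLI for shell use:

```sh
fretscope simulate --out scene/ --seed 1
fretscope run --donor scene/scene_donor.tif --fret scene/scene_fret.tif \
              --acceptor scene/scene_acceptor.tif --out analysis/
```

## Layout

- `src/fretscope/` — library modules (`synthetic`, `fret`, `segmentation`,
  `apb`, `spatiotemporal`, `morphodynamics`, `binding`, `io`, `pipeline`,
  `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite, including ground-truth recovery and
  brute-force-oracle cross-checks
- `docs/methods.md` — models, conventions, parameter choices and known
  limitations
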