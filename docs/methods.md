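# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the limits of what passing tests demonstrate.

## Rendering model of the synthetic scene generator

The generator produces the three confocal channels of a sensitized-emission
FRET experiment from a single scalar field `E(x, t)`, the true FRET
fraction (the fraction of donor excitations transferred to the acceptor):

```
donor_true      = D · (1 − E)        # quenched donor emission
sensitized_true = D · E              # acceptor emission due to FRET
acceptor_true   = A                  # directly excited acceptor
Dex-Aem channel = sensitized_true + α_D·donor_true + α_A·acceptor_true
```

with `D = donor_expression` and `A = acceptor_expression` uniform inside
the cell.  This linear model makes two useful identities exact on
zero-noise scenes: the bleed-through correction inverts the render
(`FRET_T ≡ sensitized_true`), and the donor-normalized FRET equals
`E/(1−E)`.  It deliberately ignores excited-state kinetics, donor/acceptor
photobleaching over time, expression gradients and out-of-focus light.

**Cell geometry.** A star-convex radial function
`r(θ, t) = r₀·(1 + Σ aₖ sin(kθ + φₖ)) + jitter(θ, t)` guarantees that
every segment from a boundary point to the centroid stays inside the cell,
the assumption underlying all linescan-style analyses.  The jitter is a
low-order random Fourier series per frame with amplitude
`boundary_motility_amp_px`; with `motility_activity_coupling` κ < 0 its
local amplitude is scaled by `1 + κ·(hotspot pulse)`, planting the
"active membrane is quiet" anticorrelation used in the motility tests.

**Activity field.** `E = baseline + hotspot·w(t)` inside an angular window
(default 80° centred at +45°) restricted to within
`hotspot_edge_depth_px` (default 8 px) of the boundary, plus an optional
quadratic drift.  The pulse waveform `w(t)` is a raised-cosine pulse train
(period 3.5 min, duty 0.5) by default — spectrally richer than a pure tone
so periodogram tests are non-trivial; a pure `sinusoid` (exact for on-grid
spectral checks) and a `constant` hotspot (for single-frame bleaching
pairs) are selectable.  Configurations whose pulsed maximum reaches 1 are
rejected.

**Noise.** Gaussian with variance `gain·signal` (a Gaussian approximation
to photon shot noise appropriate for the photon-counting-like detectors
this emulates) plus constant read noise `gauss_noise_sd`, clipped at zero.
Gain and read noise are free parameters (defaults 1.0 and 1.0 au); nothing
in the modelled acquisition pins them, so recovery rates quoted by the
tests are specific to these settings.

**Acceptor photobleaching pairs.** A bleach map `b ∈ [0, 1]` removes
acceptor (`post_acceptor = (1−b)·pre`) and returns the corresponding donor
emission (`post_donor = pre_donor + b·sensitized`), giving the closed-form
per-pixel recovery `100·b·E/(1−E+b·E)`, which reduces to `100·E` at
complete bleaching.  This is the oracle for all linescan tests.

**Scales.** 0.2 µm/pixel and 2 frames/min are the acquisition defaults
throughout; bleed-through defaults are α_D = 0.55, α_A = 0.028.

## FRET-index stage

The 2×2 median filter has no central pixel; the block is anchored at each
pixel's top-left corner (rows r..r+1, cols c..c+1) with edge replication —
a documented convention, configurable by applying any other filter to the
float output.  Negative FRET-index pixels are kept in the float pipeline
(over-subtraction is diagnostic of miscalibrated α) and clipped only on
8-bit export.  The 8-bit step itself is opt-in so ground-truth tests run
unquantized; a constant stack maps to all zeros under global min-max
scaling.  Calibration slopes are least-squares slopes through the origin
pooled over masked pixels, averaged across cells when several samples are
given — bleed-through is offset-free by construction, so the
through-origin form is the right estimator.

## Segmentation

Per frame: global threshold (Otsu by default; a fixed user threshold is
accepted since thresholds in the emulated workflow are user-defined) →
optional erosion smoothing (radius parameter, default 0 so clean data is
not shrunk) → hole filling → removal of components smaller than
`min_area_px` → component selection.  Multi-component frames keep the
largest component on the first frame and the component nearest the
previous centroid afterwards.  Boundaries are Moore-traced ordered
8-connected loops; chain length weights diagonal steps √2 and
overestimates a smooth perimeter by the usual small rasterization excess
(≈3% for a digital circle).  Quadrants are image-axis-aligned through the
centroid — Q1 top-left, Q2 top-right, Q3 bottom-left, Q4 bottom-right —
with on-line pixels assigned to the right/bottom side.  Coordinates are
(row, col), 0-based, pixel centers at integers; distances stay in pixels
until reporting.

## Linescan recovery profiles

Lines run from every boundary pixel to the centroid, sampled at unit steps
with bilinear interpolation (nearest-pixel optional).  The distance
coordinate is arc position along the line from its boundary endpoint, not
the Euclidean edge-distance map (both are available; the line-based form
matches the linescan definition).  Per-bin recovery applies the ratio
formula to bin-mean pre/post intensities (ratio of means) rather than
averaging per-pixel ratios — stabler when bins contain few samples; the
two differ only at second order in the intensity spread.  Default bin
width 1 px, exposed as a parameter.

## Spectral analysis

Quadratic detrend by least squares, then a one-sided periodogram with
rectangular window and no zero padding; the zero-frequency bin is
excluded and power ties resolve to the lowest frequency.  A constant
trace after detrending is an error ("no oscillatory power"), not a
silent zero.  Non-uniform sampling is rejected rather than resampled.
The cell-level period averages per-quadrant dominant periods.  Estimates
land on the frequency grid `k/T_record`, so a 3.5-min pulse in a 25-min
record reads 25/7 ≈ 3.57 min; the tests therefore assert agreement within
one frequency bin, the estimator's actual resolution.

## Sector kymographs

The sector is fixed from the first frame's geometry: an arc of
`arc_length_px` boundary pixels (default 40) centred either explicitly or
at the boundary position maximizing time-averaged near-membrane FRET_T
(scores smoothed over a 5-point circular window — the window size is a
parameter since nothing in the emulated workflow pins it).  Intensities
along the rays from arc pixels to the centroid are pooled per frame into
distance-from-edge bins, masked per frame.

## Morphodynamics and motility

Areas are foreground pixel counts; lattice areas of disks track πr² to
≲1% only for r ≳ 20 px, so analytic cross-checks use that regime.
The boundary-velocity stage is a deliberately simple, self-contained
definition (no external tracking plugin, and no claim of numerical
equivalence to any): each frame's footprint becomes a subpixel
marching-squares contour, resampled at ≈1 px arc spacing and smoothed with
a circular Gaussian (σ = 2 px) — raw binary contours zigzag by ±0.3 px and
bias nearest-distance measurements low.  Velocity at each of
`n_boundary_samples` points is the distance to the next frame's contour,
signed positive when the point lies inside the next mask (protrusion) and
negative outside (retraction); motility is the modulus.  Topology changes
(splitting/merging footprints) are outside this definition's domain.
Near-membrane activity is averaged over unit steps along the inward ray up
to 1 µm (5 px at default resolution); both grids index membrane positions
through the same sampling, so they pair one-to-one.  Activity bins are
left-closed `[3k, 3k+3)` — printed bin labels like "9–12, 12–15" share
endpoints, so a closure rule is required — and the cubic fit runs on bin
means (as such relations are conventionally plotted) with R² defined as 0
for a zero-variance response; a raw-sample fit is available.

## Binding fits

Nonlinear least squares on `Y = Bmax·X/(K_D + X)` with positivity bounds,
initialized at `Bmax₀ = max(Y)`, `K_D₀ = median(X)`; both parameters are
free.  Replicates are pooled into one residual vector by default (fitting
all points jointly), with per-replicate fits optional; no weighting is
applied.  The fit is exactly scale-equivariant in Y.  The synthetic
titration default is the five-point 75–1250 nM design with optional
multiplicative (relative) noise, the error structure typical of quantified
band intensities.

## Problem sizes and determinism

Validation suites run on 64–96 px scenes with 1–50 frames, 20–50 seeds per
stochastic property and 100 seeded repeats for the K_D error study —
sizes at which every property under test is already well resolved.  All
randomness flows through `numpy.random.default_rng` seeded from the scene
or script seed; identical seeds give bit-identical stacks and
byte-identical pipeline CSVs.

## What passing tests do and do not show

Ground-truth recovery on synthetic scenes demonstrates that the
implementation computes its stated quantities correctly under the
generator's assumptions: uniform expression, star-convex single cells,
angularly localized membrane-proximal activity, Gaussian shot-like noise.
Real movies add background structure, expression gradients, focus drift,
multiple touching cells and photobleaching trends, none of which the
generator emulates; segmentation thresholds and the boundary-smoothing
scale in particular should be re-examined on real data.  Reported recovery
rates (period detection, anticorrelation sign) are statements about the
documented synthetic conditions, not about arbitrary signal-to-noise
regimes.
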