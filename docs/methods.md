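# Methods

## Problem setting and assumptions

A fixed camera faces one row of up to six plants; frames are time-ordered
RGB images.  The pipeline assumes (i) the foreground row is the lowest plant
material in the image (it is nearest the camera), (ii) background rows
appear higher in the image and eventually overlap the foreground
silhouettes, (iii) foreground plant color is stable enough across the season
that pre-overlap pixels are representative of post-overlap foreground
pixels, and (iv) plants do not move: each foreground plant occupies a stable
column range for the whole season.

## Segmentation (plant vs soil)

The plant/soil stage is deliberately simple and pluggable: K-means (seeded,
10 restarts) on the pooled pixels of clean-background reference images,
nearest-center classification, and an excess-green rule (`2G − R − B >`
0.05, configurable) to flag plant clusters.  Any per-pixel classifier with
the same `segment(image) -> mask` surface can replace it.  The reference
images must contain all color modes the field images do — in particular
soil; a color never seen at fit time is assigned to whatever center happens
to be nearest (observed failure: soil absorbed into the green cluster).  The
synthetic greenhouse references therefore include a soil-colored floor
strip, and the pipeline fits k = 3 (plant, backdrop, soil).

## Row profiles, the first peak, and the overlap change point

Row profiles index from the **bottom** of the image up.  The first peak of
the per-row plant-proportion profile is the first local-maximum plateau (at
least 10% of the global maximum, to skip noise bumps; the bottom-most
maximal row of the plateau is the center).  Its boundaries are the first
rows below/above the center falling under `boundary_frac` (default 5%) of
the peak maximum.  Peak width is tracked per frame; after per-day median
smoothing (`day_length` timestamp units, default 1.0 so integer frame
indices pass through unchanged), a single least-squares mean-shift split is
fitted by exhaustive search, and a change point is reported only when the
mean width increases by at least `min_jump` (default 20 rows).  Ties in the
split search go to the earliest split.  `ChangePoint.frame_index` is
**1-based** (the convention of the change-point literature): it is the
position of the first post-overlap frame.

## Self-supervised training data

From the `window` (default 3) valid frames immediately before the change
point, every plant pixel at or below the first peak's upper boundary
(bottom-up) is labeled foreground, every plant pixel above it background.
Patches are cropped from the background-removed images — matching what the
classifier sees at prediction time — with zero padding beyond the image
border, and the two classes are balanced exactly by seeded subsampling to
`min(n_fg, n_bg, per_class_cap)` each (cap default 20,000).

## Patch CNN

The classifier is implemented directly on numpy (no deep-learning framework
is assumed): im2col convolutions, argmax-tracked max pooling, inverted
dropout, Glorot-uniform initialisation, Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-7), and a numerically stable fused sigmoid/binary-cross-entropy.
Backpropagation is verified against central finite differences in the test
suite.  Training is bit-deterministic under a fixed seed (fixed
initialisation, shuffling, dropout masks); dropout is inference-off, so
predictions are deterministic and batch-size invariant.  Pooling uses floor
division with no padding (33 → 16 → 8), reproducing the reference layer
sizes; patches smaller than 2 pools (r or c < 2) are rejected.  Two
training presets exist: `paper` (100 epochs, batch 1000, the full-scale
field protocol) and `desk` (10 epochs, batch 256, for desk-scale scenes).
The 5% validation split is taken from a seeded shuffle; per-epoch history
(train loss/accuracy as batch-weighted running averages, validation metrics
after each epoch) always has exactly `epochs` rows.

The neighborhood should be chosen relative to image resolution: r = c = 16
(33×33 patches) at the 1000×750 working resolution; the synthetic season is
rendered at quarter scale, so the pipeline default there is r = c = 4 (9×9),
covering the same physical extent.

## Superpixel refinement

SLIC superpixels are computed on the background-removed image (compactness
10; target region size 400 pixels at 1000×750, scaled proportionally to the
scene's resolution).  Region means are estimated from a seeded sample of
`ceil(N_i^α)` of the region's plant pixels (α default 0.7, minimum sample
10; N_i is the region's plant-pixel count), and all plant pixels of a region
are labeled foreground iff the mean exceeds 0.5 — a tie is background, and
non-plant pixels are never resurrected.

A caveat the synthetic experiments make explicit: refinement improves the
segmentation when the per-pixel probabilities are noisy (its design regime,
and the regime of real field imagery), but when the classifier is already
near-perfect — as on clean synthetic colors — regions straddling the
foreground/background canopy boundary can only flip correct pixels, so the
refined IoU (~0.93) sits slightly below the raw thresholded IoU (~0.96).
The refined masks still satisfy the pipeline's accuracy targets and are
what the height stage consumes.

## Height measurement

Early (pre-overlap) frames: the row-cut band from the first peak and
column-cut intervals (maximal column runs at ≥ `valley_frac` = 5% of the
column-profile maximum, at most `max_plants`, largest-mass kept) isolate
each plant; height is the inclusive span between its top and bottom plant
pixels.  Late (post-overlap) frames use the CNN-refined mask: the bottom-up
row-mean curve is LOESS-smoothed (local linear, span 0.1 of rows, no
robustness iterations — linear trends are reproduced exactly), the
foreground row band is bounded at the first rows under 7.5% (above the
maximum) and 2.5% (below) of the smoothed maximum, and the same column-cut
and span measurement applies within the band.

The pipeline adds one structural element: per-plant **column slots** are
estimated once from the early frames (modal column-cut count; interval
centers of the last early frame with that count; slot boundaries midway
between centers) and reused for all late frames.  Touching late-season
canopies defeat a per-frame column cut — neighbors merge into one interval —
while the fixed camera geometry makes early-derived slots valid all season.
On the default synthetic season this reduces height MAE from ~6% to ~2–3%.

Heights are reported in pixels.  An optional pinhole conversion
(`pixels_to_cm`) uses the camera constants (focal 4.5 mm, sensor
6.17 × 4.55 mm, row distance 213.4 cm): one pixel row spans
`sensor_height / image_rows` on the sensor, times `distance / focal` at the
plant row (100 px ≈ 28.8 cm at 750 rows).  It is opt-in because measured
units depend on a calibration the imagery may not carry.

## Growth curves and FPCA

Monotone fits use smooth-then-project: a Gaussian local-linear smoother
(bandwidth by Silverman's rule on the observation times, `0.9·min(sd,
IQR/1.34)·n^{-1/5}`, unless given) evaluated on a 100-point grid over the
observed range, then the pool-adjacent-violators projection (via
`sklearn.isotonic`) onto nondecreasing sequences — the least-squares
closest monotone curve to the smoothed values.  With smoothing disabled the
fit is the pure isotonic regression of the time-ordered observations.
Grid points far from all observations fall back to the local-constant fit
where the local-linear design is singular.

FPCA eigen-decomposes the quadrature-symmetrised sample covariance
`W^{1/2} C W^{1/2}` (trapezoid weights W, ddof = 1) so the eigenfunctions
are orthonormal in L² on the grid (Gram error < 1e-8 by construction);
scores are trapezoid inner products of the centered curves with the
eigenfunctions.  Signs are fixed so each eigenfunction's integral (or its
last grid value when the integral is numerically zero) is positive, making
recovery tests deterministic.  K is the smallest number of components
reaching the variance threshold (default 0.95) unless fixed.  Zero-variance
input returns a flagged degenerate result (`degenerate_ = True`, K = 0)
rather than raising.

## The synthetic world

The generator renders what the pipeline consumes and nothing more: logistic
per-plant growth (per-plant maximum height, rate and midpoint drawn from
configured ranges), stem-and-leaf polygon silhouettes, a foreground baseline
low in the image and a background row based higher with thinner strokes
(the smaller apparent scale of a farther row), soil elsewhere, iid Gaussian
pixel noise (sd 0.03), and — by default — *identical* color distributions
for foreground and background plants, so separation must come from
geometry, as in the real problem; a color-shift knob exists for ablation.
Truth masks, the first row-sharing frame (the overlap), and per-plant
silhouette heights are exact by construction.  The default season is
250×188 px (quarter of the working resolution), 60 frames, 4 foreground and
6 background plants.

What a green test does **not** establish: robustness to illumination drift,
shadows, wind motion, occlusion by equipment, senescence color change, or
segmentation noise of real field imagery — none of which are simulated.
The CNN's field accuracies reported for real data depend on that imagery
and are not reproduced here.

## Known limitations

- A single change point; storms or camera moves that shrink the first peak
  are out of scope.
- The plant-slot registry assumes plants neither move nor die mid-season.
- The cm conversion ignores lens distortion and the camera's height/tilt.
- FPCA operates on curves restricted to a common observed span; no
  extrapolation beyond the season (fitted curves need not flatten).
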