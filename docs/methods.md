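# Methods

This note documents the detection pipeline, its committed parameters, the
synthetic study conditions, and the numerical and design choices a
maintainer needs to reason about results.

## Pipeline

### Colour normalization

Bright-field transmitted-light images multiply a smooth illumination field
into every pixel.  The field is estimated per channel as the *bright
envelope*: morphological opening of the absorbance complement `1 − I` with
a disk of radius 50 px (30 µm at 0.6 µm/px — larger than nuclei and single
cells, so cellular structure is erased), which equals a grayscale closing
of the intensity image.  Correction is multiplicative flat-field division,
`out = I / max(bg, 1e−3) · mean(bg)`, clipped to [0, 1].  The direction of
the envelope matters: a *dark* envelope (plain opening of intensity) tracks
nuclear darkness rather than the lamp profile in tissue imagery and inverts
the lumen/tissue brightness ordering after division; the bright envelope is
the transmitted-light profile the lamp actually produces.  The estimate is
well-posed whenever pale structure (lumen, crypt lumina, mucin) occurs
within every structuring-element window — true of colonic mucosa and of the
generator below.  Within half a structuring-element radius of the frame
border the envelope is distorted by boundary padding; quantitative checks
of gradient removal therefore measure the interior.

After correction, each channel is quantile-mapped onto a reference
distribution (256 anchors, linear interpolation, rank ties averaged)
sampled from one designated corrected image — by default the
lexicographically first image id.  Preprocessing is fixed by configuration
before any training, and the only cross-image statistic is that single
fixed reference, which is shared by all folds of every protocol.

### Segmentation and features

SLIC (scikit-image implementation; CIELAB colour space) partitions each
image into ~k superpixels seeded on a grid of spacing S = √(N/k); k = 1000
for the nominal 1392 × 1040 frame (S ≈ 38 px) and is scaled by image area
for smaller fields of view so the physical superpixel size is preserved.
Compactness defaults to 10.  Connectivity enforcement merges fragments
below 0.2 · N/k pixels; the stricter classical choice S²/4 was measured to
absorb the thin band-following superpixels (the band is ~25 px thick
against S ≈ 38 px) and break band connectivity, so 0.2 is the committed
default (configurable).  The superpixel adjacency graph uses 8-connectivity
(configurable to 4) so diagonally touching band segments count as
connected.

Features are per-channel histograms over 32 equal-width bins on [0, 1]
(half-open, last bin closed), each channel block normalized to sum 1,
concatenated R‖G‖B (96 values).  Tissue-free white superpixels are excluded
before labelling: a single global Otsu threshold on luminance (channel
mean) flags superpixels whose above-threshold fraction exceeds 0.8.  On a
constant image Otsu is undefined and no superpixel is flagged.

### Labelling, augmentation, split

A superpixel is *disease* when ≥ 70 % of its area lies inside the rough
expert annotation.  The minority class is oversampled to the majority count
(policy configurable) by copying seeded-uniformly-chosen minority rows,
adding i.i.d. uniform noise in [−0.15, 0.15] per bin, clipping at zero and
renormalizing each channel block; originals are never modified.  The 80/20
train/validation split is a seeded uniform split of *real* rows; augmented
rows always follow their parent, so perturbed copies of a validation
superpixel cannot leak into training.

### Classifier

Input standardization (training-set mean and population 1/n standard
deviation, scale floored at 1e−8), three hidden layers of ten tanh units,
softmax over {normal, disease}.  Weights start from a seeded symmetric
uniform fan-based (Glorot) scheme; the mean categorical cross-entropy is
minimised with L-BFGS (scipy `L-BFGS-B`, memory 10, gradient tolerance
1e−6, at most 1000 iterations) using the exact backpropagation gradient.
No regularization by default; an L2 penalty on weight matrices is exposed
in configuration.  Prediction is the softmax argmax with an exact 0.5 tie
resolved to *normal* — the conservative call for a screening aid.  Training
is deterministic given data, seed and configuration.

### Post-processing

Predicted-disease superpixels are grouped into connected components on the
adjacency graph; components with fewer than ten superpixels (~10,000 px at
nominal scale) are removed, since CC presents as a continuous band, not
isolated islands.  Component connectivity is superpixel-graph connectivity,
not pixel-level analysis of the rendered mask.

### Evaluation

Superpixel metrics are accuracy, sensitivity and specificity from 2×2
counts with disease positive; undefined ratios are reported as undefined,
never coerced to zero.  Pooled figures are micro-averages of summed counts.
Two protocols:

* **80/20 split** — one model on all superpixel rows, scored on the real
  validation rows.  This is the protocol behind classifier-level headline
  metrics.  The size filter is not part of this score: it operates on whole
  images, while split validation rows are scattered across images.
* **Leave-one-image-out** — per fold, augmentation, standardizer and
  network are refitted on the other images only (asserted structurally),
  the withheld image is predicted and post-filtered.  The report carries
  both the classifier-level pooled metrics and the post-filter pooled
  metrics, plus an image-level *acceptability proxy*: 1 when the final
  mask reaches IoU ≥ 0.5 against the ground-truth band.  The proxy is an
  automated surrogate for expert acceptability scoring, which is a human
  endpoint outside the scope of this package and not claimed reproducible.

## Synthetic study conditions

The generator emulates a 20× H&E colonic biopsy field (0.6 µm/px).  Layer
geometry, top to bottom: lumen (30 % of frame height, near-white
0.97/0.96/0.97), columnar surface epithelium (25 µm — the height of real
colonocytes — eosinophilic cytoplasm 0.68/0.50/0.72 with a 4 px dark basal
nuclear row), the collagen band (default 15 µm = 25 px; glassy
0.85/0.66/0.81, sd 0.02; demarcated below by a 4 px capillary/nuclear
fringe, as in real CC where capillaries are entrapped at the band's lower
border), and lamina propria (0.82/0.60/0.74, correlated texture sd 0.035,
peppered with dark stromal-cell nuclei at 0.002/px² and pale crypt/mucin
gaps at 0.0007/px²).  The mucosal contour undulates with two low-frequency
harmonics; a multiplicative illumination gradient (amplitude 0.10, random
direction) and per-sample colour jitter (± 0.015) emulate acquisition and
staining variability.  Optional artifacts reproduce the classic
false-positive confounders: a blood vessel, a white tear, a dark fold; they
are off by default and their masks are recorded for failure-mode analysis.

The discriminative structure is the published one: the band is brighter per
channel and far less dispersed than the lamina propria.  The palette keeps
band luminance below the Otsu lumen/tissue split so that the white-exclusion
rule does not swallow the band, which constrains how bright the band can be
relative to the lumen — in real slides the same constraint holds (collagen
is pink, empty slide is white).

The rough annotation is the truth band dilated by a 12 px radius whose
magnitude wanders slowly (± 40 %, low-frequency along the band) as a coarse
brush sweep would.  Twelve pixels (7.2 µm) was chosen so that (a) nearly
all band-dominated superpixels pass the 70 % overlap rule — the labelling
rule is exercised non-trivially, which fails at markedly smaller radii
because the annotated strip becomes thinner than one superpixel row — and
(b) the disease-class prevalence among tissue superpixels (~21 %) matches
the published cohort (65,664 of 295,801 ≈ 22 %).

Test-scale benchmarks use a 348 × 260 px field of view (quarter linear
scale) at the same resolution with k = 62 (area-scaled), chosen to keep
the full benchmark under a minute on one CPU; the problem sizes are 24
images for the split protocol and 12 for leave-one-out.

### What the synthetic conditions do and do not show

Passing benchmarks demonstrate that the pipeline's stages compose
correctly, that the classifier learns the intended brightness/dispersion
contrast from weak labels, that fold isolation is airtight, and that the
spatial filter behaves as specified.  They do not demonstrate clinical
performance: real H&E exhibits stain variability, focus and compression
artifacts, crypts cutting through the band plane, inflammation, and
annotation idiosyncrasies that the generator only caricatures.

One structural property of the quarter-scale geometry deserves emphasis:
a band chain spans only ~9–15 superpixels (the frame is ~9 grid columns
wide), while the component filter keeps chains of ≥ 10 *unscaled* — at full
scale the same band would span ~36+ columns and pass comfortably.  At
quarter scale single classifier misses, or single band superpixels flagged
white, can therefore drop a whole detection.  This is visible in the
leave-one-out report as the gap between the classifier-level pooled
accuracy (~0.95) and the post-filter pooled accuracy (~0.84–0.89), and in
the conservative acceptability-proxy fractions.  The filter threshold is
deliberately left at its published value rather than rescaled.

## Numerical choices and degenerate inputs

* Intensities are float64 in [0, 1]; 8-bit assumed on write, 8/16-bit
  accepted on read; greyscale and alpha rasters are rejected, never
  coerced.
* Flat-field divisor floored at 1e−3; standardizer scale floored at 1e−8
  (constant features standardise to zero); log of an exactly-zero softmax
  probability is guarded.
* Quantile-map CDF positions use average ranks; anchors are linearly
  interpolated.
* Histogram bins are half-open with the final bin closed at 1.0.
* Connected components are identified by their smallest member label;
  fragment-merge ties in SLIC follow the scikit-image implementation.
* Empty/full masks are legal and flagged; an empty annotation labels every
  superpixel normal; a constant image disables background exclusion with a
  warning.
* All stochastic stages (augmentation parent choice and noise, splits,
  weight initialisation, per-sample generator streams) draw from seeds
  derived from one master seed via `numpy` seed sequences; fixed seeds give
  bit-identical models and reports.

## Known limitations

* Band thickness morphometry and crypt-orientation assessment are not
  implemented (out of scope); the tool highlights band-associated regions
  and is not a diagnostic classifier.
* The histogram-alignment variant is one faithful reading of channel-wise
  histogram alignment; the original method's exact formulation is not
  public.
* MATLAB's `superpixels` internals are not reproduced bit-for-bit;
  equivalence with the published segmentation is at the contract level
  (seeded grid, compactness-weighted local k-means, enforced connectivity).
* Whole-slide formats, stain deconvolution and ICC colour management are
  out of scope.
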