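# ccband

Superpixel-based detection of the **subepithelial collagen band** in
H&E-stained colonic biopsy micrographs — a decision-support aid for the
histopathological assessment of collagenous colitis (CC).

CC is defined by a thickened (≥ 10 µm) collagen layer directly beneath the
surface epithelium.  On routine H&E the band is a glassy eosin-pink strip
that can be subtle in borderline or heterogeneous specimens.  `ccband`
highlights band-associated regions on standard 20× bright-field micrographs
(nominally 1392 × 1040 px at 0.6 µm/px) without collagen-specific stains,
and trains from coarse, region-level annotations rather than pixel-precise
labels.

## Method

1. **Colour normalization** — per-image illumination correction by
   flat-field division with a morphological bright-envelope background
   (disk structuring element larger than cellular structures), followed by
   channel-wise quantile alignment to a fixed reference image.
2. **SLIC superpixels** — each image is partitioned into ~*k* = 1000
   compact regions (scaled by area for smaller fields of view); the seed
   grid spacing is *S* = √(*N*/*k*) for an *N*-pixel image.
3. **Features** — per superpixel, the concatenation of normalized per-channel
   RGB histograms (32 bins each).  Band superpixels show higher intensities
   and lower dispersion than surrounding tissue.  White, tissue-free
   superpixels are excluded by a global Otsu luminance rule.
4. **Weak labels** — a superpixel is *disease* when ≥ 70 % of its area
   overlaps the expert's rough band annotation.
5. **Classifier** — a feed-forward network *F* → 10 → 10 → 10 → 2 with tanh
   hidden units and softmax output, trained by minimising cross-entropy
   with L-BFGS on standardized inputs; the minority class is balanced by
   oversampling with bounded uniform histogram noise (± 0.15, renormalized).
6. **Post-processing** — predicted-disease superpixels are grouped on the
   region adjacency graph and connected components with fewer than ten
   superpixels are removed, enforcing the spatial continuity of a real band.

A synthetic generator (`ccband.synthetic`) produces H&E-like colonic mucosa
micrographs — lumen, columnar epithelium, collagen band, cell-busy lamina
propria, optional vessel/tear/fold artifacts — with exact band masks and
emulated rough annotations, so the whole pipeline is testable without
clinical data.

## Worked example

```python
import dataclasses
from ccband import CollagenBandModel, PipelineConfig, SyntheticSpec, generate_dataset
from ccband.segmentation import scaled_superpixel_count

spec = SyntheticSpec().quarter_scale()        # 348 x 260 px at 0.6 um/px
cfg = PipelineConfig()
cfg.slic = dataclasses.replace(
    cfg.slic, k=scaled_superpixel_count(spec.height_px, spec.width_px))

samples = generate_dataset(spec, 24, seed=42)
results = CollagenBandModel.from_synthetic(samples, cfg).fit(seed=42)
print(results.summary())
```

```
Collagen-band detection model
================================================================
images                  24
superpixels             1538 (428 background-excluded)
labelled rows           233 disease / 877 normal (+644 augmented)
train / validation      1412 / 342
----------------------------------------------------------------
network                 96 -> 10 -> 10 -> 10 -> 2 (tanh, softmax)
optimiser               L-BFGS, 88 iterations, final loss 0.00000
----------------------------------------------------------------
validation accuracy     0.9505
validation sensitivity  0.9111
validation specificity  0.9605
```

The validation block reads: of the real superpixels held out by the seeded
80/20 row split, 95.1 % were classified correctly; 91.1 % of true
band-associated superpixels were detected (sensitivity) while 96.1 % of
normal-tissue superpixels were left alone (specificity).  Detection on a
new image returns the raw per-superpixel calls, the surviving connected
components and the rendered mask:

```python
det = results.predict(samples[0].image)
print([len(c) for c in det.surviving])        # e.g. [13] — one band chain
```

Leave-one-image-out evaluation (`results` trained per fold on the other
images only) is available as
`CollagenBandModel.from_synthetic(samples[:12], cfg).leave_one_out(seed=42)`.

## Command line

```bash
ccband simulate --n 12 --seed 42 --out sim/          # synthetic samples
ccband train    --images imgs/ --masks masks/ --out model.json
ccband predict  --image imgs/s0.png --model model.json \
                --out-mask mask.png --out-overlay overlay.png
ccband evaluate --images imgs/ --masks masks/ --report report.json
ccband run-all  --out run/ --n 12 --seed 42          # end to end
```

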