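# eatseg

Automated segmentation and quantification of **epicardial adipose tissue
(EAT)** in four-chamber (4Ch) cardiac cine MRI.

EAT — the fat enclosed between the myocardium and the pericardium — is a
metabolically active depot linked to coronary disease, diabetes and atrial
fibrillation, but it is routinely ignored because contouring it per frame is
tedious. Its 2D area in the standard 4Ch cine view is a practical surrogate
for total EAT volume. The hard part is telling EAT apart from **paracardial
adipose tissue (PAT)** just outside the pericardium: both are bright fat on
bSSFP cine, separated only by a ~2 mm fascia — about one pixel at clinical
resolution (1.3–1.8 mm). What distinguishes them is *motion*: EAT is attached
to the myocardium and moves with contraction, while PAT stays near-static.

`eatseg` implements the full pipeline for a multi-frame segmentation
approach that exploits exactly this cue, plus a synthetic cine phantom so
every stage is testable without clinical data:

* **`phantom`** — synthetic 4Ch cine generator: contracting ventricle disk +
  myocardial ring (one HV class), an EAT layer riding on the epicardial
  boundary with a per-angle thickness profile (sparse isles allowed), a thin
  pericardial gap, loosely motion-coupled PAT blobs, partial-volume mixing,
  polynomial bias field, noise; cohorts of healthy / obese / type-2 diabetic
  subjects whose latent EAT volume drives the rendered EAT area.
* **`dataio`** — NIfTI I/O, per-series [0,1] normalisation, centered
  pad/crop to the network grid (invertible), 3-frame cyclic windows, and
  stratified 5-subset splitting for 4-fold cross-validation.
* **`augment`** — clipped-normal rotation (±30°) and scaling (0.4–1.6).
* **`nets`** — two multi-frame fully convolutional networks mapping a
  3-frame window to a 4-class (background/EAT/PAT/HV) probability map for
  the central frame: a U-Net (skip connections, 48→768 features over 5
  levels) and FCNB (all encoder scales upsampled to full resolution and
  fused). The first layer is a temporal convolution with valid padding that
  collapses the 3 frames. Implemented directly on numpy with manual
  backpropagation.
* **`training`** — soft dice loss over the three foreground classes
  (background excluded), Adam at a constant 1e-3, batch 30, on-the-fly
  augmentation, best-validation checkpointing, 4-fold cross-validation.
* **`metrics`** — DSC, mean surface distance (mm), absolute relative
  surface error (%), positive predictive value; Shapiro–Wilk and Wilcoxon
  comparisons.
* **`analysis`** — EAT area, quartile risk classification with 4×4
  confusion summaries, area–volume regression, and keyframe label
  propagation by multi-resolution demons registration.

## Worked example

```python
import numpy as np
from eatseg import phantom, analysis, metrics
from eatseg.metrics import BinaryMask

# one synthetic subject: 64x64, 25 frames, noise + bias field on
params = phantom.PhantomParams(seed=4)
series, labels, systole, diastole = phantom.render_cine(params)
sp = (params.pixel_spacing, params.pixel_spacing)
area_dia = analysis.area_cm2(labels.masks[diastole] == 1, sp)
area_sys = analysis.area_cm2(labels.masks[systole] == 1, sp)
print(f"EAT area: {area_dia:.2f} cm^2 at diastole, {area_sys:.2f} cm^2 at systole")

# propagate the three annotated keyframes to all 25 frames
keyframes = {0: labels.masks[0], systole: labels.masks[systole],
             19: labels.masks[19]}
propagated, info = analysis.propagate_labels(series, keyframes)
dices = [metrics.dsc(BinaryMask(labels.masks[t] == 1, sp),
                     BinaryMask(propagated.masks[t] == 1, sp))
         for t in range(25) if t not in keyframes]
print(f"propagated EAT dice over {len(dices)} frames: "
      f"min {min(dices):.3f}, mean {np.mean(dices):.3f}")

# cohort-level: EAT area vs latent volume
cohort = phantom.sample_cohort(30, seed=0)
report = analysis.correlate_area_volume(
    [s.eat_area_cm2["systole"] for s in cohort],
    [s.true_eat_volume for s in cohort], frame_role="systole")
print(f"area-volume Pearson r = {report.pearson_r:.2f} (n = {report.n})")
```

prints

```
EAT area: 2.61 cm^2 at diastole, 1.80 cm^2 at systole
propagated EAT dice over 22 frames: min 0.840, mean 0.898
area-volume Pearson r = 0.87 (n = 30)
```

The EAT area is smaller at systole because the fat layer rides inward on the
contracting epicardial boundary; the propagated masks emulate how three
expert-annotated keyframes (first phase, peak systole, late diastole) are
carried to the remaining cine frames by nonrigid registration; the cohort
correlation reflects the built-in monotone link between a subject's latent
EAT volume and its rendered 4Ch area.

A command-line interface wraps the same functions:

```bash
eatseg simulate --n 100 --out cohort/ --seed 7     # synthetic cohort + manifest
eatseg segment  --weights ckpt.npz --cine cohort/sub-000_cine.nii.gz --out labels.nii.gz
eatseg evaluate --pred preds/ --truth cohort/ --manifest cohort/manifest.csv --out metrics.csv
eatseg quartiles --metrics metrics.csv --out quartiles.json --figure confusion.png
```

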