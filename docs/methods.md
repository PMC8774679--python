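# Methods

## The problem and the modelling idea

Epicardial adipose tissue (EAT) lies between the myocardium and the
pericardium; paracardial fat (PAT) lies just outside. On bright-blood bSSFP
cine both are hyperintense and the pericardial fascia separating them is
about 2 mm thick — the same order as the in-plane pixel (1.3–1.8 mm), so a
single-frame segmenter has almost no static evidence to tell them apart.
The discriminating signal is temporal: EAT is mechanically attached to the
myocardium and moves with contraction, PAT barely moves. The networks here
therefore consume **three consecutive cine frames** and segment the central
one; the first layer is a convolution over (x, y, t) with valid temporal
padding, which for a 3-frame window is algebraically a 2D convolution with
one distinct spatial kernel per frame. Frame order genuinely changes the
output, so temporal derivatives are available to the network from layer one.

Four classes are predicted per pixel: background, EAT, PAT and HV (heart
ventricles: ventricular muscle plus blood pools as one class). Two decoder
designs are provided over a shared encoder (two 3×3 conv + batch norm +
ReLU blocks per level, 2×2 max pooling, features doubling from
`first_layer_filters`, default 48 up to 768 at five levels):

* **U-Net** — upsample (factor-2 bilinear + 3×3 conv), concatenate the skip
  connection, two conv blocks, repeated up to full resolution;
* **FCNB** — every level's final feature map is upsampled directly to the
  input resolution, all are concatenated and fused by two 3×3 conv blocks.

A 1×1 convolution and per-pixel softmax produce the probability map. Both
networks are fully convolutional; any spatial size divisible by
2^(levels−1) is accepted.

The stack is implemented directly on numpy (im2col convolutions with exact
manual backpropagation, verified against finite differences in the test
suite). Checkpoints are `.npz` plus a JSON sidecar with the architecture
config and seed.

## Loss, optimisation and a necessary initialization choice

Training minimises one minus the mean **soft dice over the three foreground
classes**; the background channel exists in the softmax but carries no loss
term. Per class c, dice = (2·Σ p_c·t_c + ε)/(Σ p_c + Σ t_c + ε) with
ε = 1e-6, summed over the whole batch and all pixels — batch-level
aggregation is markedly stabler than per-sample dice when EAT is a sparse
sliver. Optimisation is Adam at a constant 1e-3, batch 30, with on-the-fly
clipped-normal augmentation; the checkpoint with the best validation
foreground mean dice is kept. All randomness (init, shuffling,
augmentation) flows from one master seed through named substreams.

Because the loss has no background term, a randomly initialised network can
enter a failure mode where one foreground class floods the background: its
overlap numerator stays near zero, so the corrective gradient on background
pixels (∝ numerator/denominator²) is also near zero, and the flood persists
for many epochs. The remedy used here is **background-prior
initialization**: the head's background bias starts at +2, so the initial
prediction is background-dominant everywhere and foreground probability
grows outward from true-overlap regions, where the gradient is informative.
With it, all three classes converge reliably within ten epochs at desk
scale; weights are otherwise He-uniform, seeded.

## Evaluation metrics

For manual mask S_M and automatic mask S_A on one frame:

* **DSC** = 2|S_M∩S_A|/(|S_M|+|S_A|); both-empty = 1 by convention.
* **MSD** (mm) = symmetric mean distance between boundary pixels (mask
  pixels with an 8-connected neighbor — or the image border — in the
  complement), center-to-center, anisotropic spacing honored. Verified
  exactly (≤1e-9) against an all-pairs brute-force oracle.
* **RSE** (%) = 100·||S_M|−|S_A||/|S_M|, areas spacing-aware.
* **PPV** = |S_M∩S_A|/|S_A| (≪1 flags over-segmentation).

Empty-mask policy: one-empty DSC = 0; MSD, PPV (and RSE with an empty
manual mask) are *flagged missing* (NaN), never coerced to 0 or ∞, so
degenerate frames cannot silently skew cohort means. Hausdorff distance is
deliberately not provided: a single outlier pixel dominates it, which is
uninformative for thin, patchy fat. Distribution comparisons use
Shapiro–Wilk for normality plus Wilcoxon signed-rank (paired) or rank-sum
(unpaired), two-sided, without multiple-testing correction (p-values are
reported raw, as is conventional for these paired segmentation comparisons).

Rows are produced per subject/label/frame-role (systole, diastole) for EAT,
PAT, merged pericardial fat (EAT+PAT) and HV; merged-fat rows use the area
of the merged mask, not the sum of per-class areas.

## Quartile risk classification and area–volume link

Subjects are banded by quartiles of *manually measured* EAT area; cuts are
linear-interpolation percentiles (25/50/75). Band assignment is closed on
the right — Q1 < q1 ≤ Q2 < q2 ≤ Q3 < q3 ≤ Q4 — so a subject exactly at a
cut lands in the upper band; with all areas equal, every subject is Q4. The
4×4 manual-vs-predicted confusion matrix is summarised as diagonal %,
off-by-one %, off-by-two % and off-by-three % (reported separately, never
folded together). Area–volume association is ordinary least squares of 4Ch
area (cm²) on volume (cm³) with Pearson r, reported separately at systole
and diastole.

## Label propagation

Experts annotate three keyframes (first phase, peak systole, late
diastole); the remaining frames are labelled by registering the nearest
keyframe image (cyclic time distance, ties to the earlier frame) to the
target and warping the keyframe labels nearest-neighbor. The displacement
estimator is pluggable; the default is a multi-resolution demons scheme
with symmetric intensity forces, Gaussian-smoothed updates (fluid σ = 1.5
px) and field (diffusion σ = 0.5 px), 60/60/80 iterations over three
scales, run on 2× bilinearly upsampled images for sub-pixel accuracy on the
one-pixel-wide fascia and fat layers. Estimator failure falls back to
copying the keyframe labels, with a warning and a per-frame record. A
byte-identical source and target frame short-circuits to an exact copy.

## The synthetic phantom: what it emulates, and what it does not

The phantom reduces 4Ch anatomy to the properties the method actually
exploits, at desk scale:

* geometry: blood disk (radius 14.5 mm at diastole) inside a 4 mm
  myocardial ring, both labelled HV; an EAT layer on the epicardial
  boundary with a per-angle thickness profile (an asymmetric main patch
  plus a small isle; zero on arcs, giving the sparse isles that make
  low-burden subjects hard); a 2 mm pericardial gap rendered at fascia
  intensity; PAT blobs outside the gap;
* motion: ventricular radius follows a cosine cycle (diastole frame 0,
  systole near mid-cycle; default contraction fraction 0.25). EAT rides
  rigidly on the epicardial boundary; each PAT blob moves by
  `motion_coupling` (defaults 0.1 and 0.25) times the local myocardial
  displacement, along its radial direction;
* signal: bSSFP-like contrast (fat 1.0 > blood 0.85 ≫ myocardium 0.30 >
  fascia 0.20 > background 0.05), area-weighted partial-volume mixing from
  3×3 sub-pixel sampling, a multiplicative second-order polynomial bias
  field (±10%), Gaussian noise (σ = 0.03); labels classify pixel centers,
  noise-free;
* cohort: groups healthy/obese/diabetic (default mix 21/12/67%), latent
  total EAT volume lognormal per group (medians 70/90/110 cm³, log-sd
  0.30/0.35/0.45 — spanning roughly 30–380 cm³ across a 100-subject
  cohort). The EAT thickness scale is solved in closed form so the analytic
  4Ch area equals 2.2 cm² per 100 cm³ of volume times a lognormal-style
  link noise (sd 0.33, calibrated so the population area–volume Pearson r
  is ≈0.8, matching the strength of association the method is meant to
  recover); a strictly monotone soft cap above 7 cm² keeps extreme subjects
  inside the grid without creating ties. Per-subject pixel spacing is drawn
  uniformly from 1.3–1.8 mm. Manifest areas are measured from 9× sub-pixel
  coverage so the volume→area link is not quantised to whole pixels.

Not emulated: MR physics (bSSFP banding, GRAPPA aliasing, flow), realistic
four-chamber anatomy (atria, valves, chest wall), through-plane motion,
observer variability, and the 3D short-axis stack (volume stays a latent
manifest number). Passing tests on the phantom therefore demonstrate that
the pipeline's machinery — multi-frame learning, metrics, stratification,
quartiles, propagation — is correct and internally consistent, not that any
particular accuracy will transfer to clinical cine.

Two rasterization caveats are deliberate: sub-pixel-thin EAT renders as a
sprinkle of pixels whose centroid is aliasing-noisy, so the differential
EAT-vs-PAT motion property is asserted on a well-resolved phantom
(0.75 mm/px); and pixel-count areas quantise, so manifest areas use
sub-pixel coverage.

## Scaled-down study conditions

Desk-scale training uses a 40-subject cohort on a 64×64 grid, a U-Net with
8 first-layer filters and 3 levels, 10 epochs, batch 30, one rotation of
the stratified 5-subset split (24 train / 8 validation / 8 test subjects,
25 frames each). Augmentation is disabled for this check: the phantom's
pose is fixed by construction, so geometric augmentation only slows
convergence without testing anything additional at this scale. The full
clinical-scale configuration (256×192, 48 filters, 5 levels, augmentation
on) is exercised for shape/probability contracts and is the default
elsewhere.

## Numerical choices

* Normalisation is per-series (not per-frame) so inter-frame signal changes
  survive into the multi-frame input; constant series are rejected.
* Pad/crop to the network grid is centered per axis with a recorded
  placement, inverted before any metric so evaluation happens in native
  space.
* 3-frame windows index cyclically (retrospectively gated cine is
  periodic): frame 0's window is (T−1, 0, 1); every frame is central
  exactly once.
* Fold splitting deals each (seeded-shuffled) group across subsets by
  largest remainder, granting remainders to the currently smallest subsets:
  subset sizes stay equal and every subset's group counts are within one
  subject of exact stratification.
* Argmax ties in inference resolve to the lower class index (background
  first), bit-reproducibly.
* Bias correction default is a self-contained surrogate — divide by the
  unit-mean least-squares 2nd-order polynomial surface fitted to the
  temporal-mean image; it recovers smooth multiplicative fields exactly on
  flat phantoms but will also flatten genuine large-scale anatomy contrast,
  so `external_n4` (SimpleITK) is preferred when available; the phantom
  training pipeline skips bias correction altogether (its rendered bias is
  mild and identical in distribution across train and test).
* Soft-dice ε = 1e-6; gradients of the loss are analytic and
  finite-difference-verified.
* Quartile cut percentiles use linear interpolation (deterministic,
  matches `numpy.percentile`'s default).

## Known limitations

* PAT/EAT discrimination at desk scale rests on the phantom's idealised
  contrast and motion; no claim is made about clinical accuracy.
* The demons estimator assumes modest displacements (a few pixels between
  neighboring keyframes); large-motion series would need the pluggable
  estimator replaced by a stronger registration.
* The numpy networks are CPU-bound and intended for desk-scale experiments;
  the architecture definitions, not their speed, are the point.
* The polynomial bias surrogate is a stand-in for N4 on structured images —
  adequate for the phantom's smooth fields only.
* `compare_distributions` reports raw p-values; apply your own correction
  when screening many labels/metrics at once.
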