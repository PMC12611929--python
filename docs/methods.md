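# Methods

`kneegrade` implements a complete computer-aided pipeline for
Kellgren–Lawrence (KL) grading of knee osteoarthritis from bilateral AP
knee radiographs: automated isolation of each knee from the shared film,
patient-level leakage-free splitting with augmentation, a transfer-learning
style CNN classifier with exact parameter accounting, the standard
evaluation metrics, and — because real KL-graded collections are rarely
shareable — a phantom-radiograph generator that makes every stage testable
end to end.

## Phantom radiographs

Each phantom emulates the cues a radiologist grades on and the nuisances a
segmentation pipeline must survive:

- two bright bone structures per image (femur block above tibia block),
  placed in disjoint column bands (~8–42% and ~58–92% of the width);
- a joint-space gap between the blocks whose height shrinks with grade:
  12, 12, 8, 4, 1 px for KL 0–4 (joint-space narrowing). Grades 0 and 1
  share one gap by construction;
- marginal osteophytes — bright half-ellipses protruding laterally at the
  joint margins — counting 0, 0, 1, 2, 4 for KL 0–4. Their semi-axes scale
  with the image (≈ h/33 × w/40) so they remain visible after the pipeline's
  resize to 224², and successive osteophytes occupy staggered sites
  (joint-line lateral, joint-line medial, femoral margin, tibial margin) so
  each count produces a distinct silhouette. Counts, unlike gap heights,
  are invariant to the zoom/rotation augmentation, which is what makes
  grades 2–4 separable by construction;
- a text-like annotation block (strokes ≤ 1 px thick inside a 12×60 px
  corner region), additive Gaussian noise (σ = 5 gray levels on a
  background of 15 against bone at 200), and ±15% per-image size jitter
  around 400×600.

KL grade 0 and grade 1 are rendered from *identical* geometry: clinically,
grade 1 is a radiographically normal knee in a patient reporting pain, so
the label difference is carried by a latent boolean pain flag that never
touches the pixels. Two-sample KS tests on mean bone intensity and measured
gap across 200 knees per class do not reject equality (this is asserted in
the test suite). Any image-only classifier should therefore sit at chance on
the 0-vs-1 boundary — the central evaluation caveat this package
reproduces.

Cohorts draw per-knee grades i.i.d. from a configurable class mix. The
default mix is the clinical per-grade tallies 18/67/105/126/86
renormalised; those tallies overcount the 301-patient cohort they
describe, so they are used only as proportions and never asserted. Ages
are uniform on [40, 80]; the same seed yields a bit-identical cohort
(SeedSequence fan-out per record).

What the phantom does *not* emulate: trabecular bone texture, soft tissue,
exposure variation, patient positioning, subchondral sclerosis, and the
continuous character of real joint-space narrowing. Passing the suite
therefore demonstrates that the pipeline and training machinery behave
correctly on images carrying the stated cues, not that the classifier
reaches any particular accuracy on clinical radiographs.

## Knee isolation

One bilateral radiograph becomes two normalized single-knee slices:

1. **standardize** — luminance grayscale conversion and bilinear resize to
   224×224 (8-bit range preserved; already-conforming input passes through
   untouched).
2. **sharpen** — unsharp mask `img + amount·(img − G_σ(img))`, defaults
   amount 1.0, σ 1.0 px, clipped to [0, 255]. Applied between
   standardization and thresholding; whether the sharpened or the plain
   image feeds each downstream consumer is config-exposed
   (`sharpen_feeds_threshold`, `crop_sharpened`).
3. **Otsu threshold** — 256-bin histogram, threshold maximizing the
   between-class variance, smallest maximizer on ties; foreground is
   `pixel > t` (bone is radiopaque, hence bright). A constant image is a
   degenerate histogram and an error.
4. **morphological opening** — binary erosion then dilation with a 5×5
   square (config-exposed). Removes specks and the thin annotation
   strokes; kept bone regions are unaffected. Opening is idempotent
   (property-tested).
5. **column detection** — per-column foreground counts; maximal nonzero
   runs; runs separated by fewer than `min_gap` (5) empty columns are
   bridged; runs shorter than `min_run` (10) columns are dropped; the two
   largest-area runs, ordered left to right, are the knees. Fewer than two
   runs raises a "knee separation failed" error carrying the run list.
6. **pixel correction fallback** — on failure, rows of the mask whose
   pixels are all equal are zeroed (`fix_identical_rows`, idempotent) and
   detection is retried; an optional midline fallback then splits at the
   widest empty gap nearest the image center.
7. **crop** — each interval's columns, rows trimmed to the foreground
   extent ± 2 rows (the row rule is this package's choice; only column
   detection is canonical).
8. **pad and normalize** — zero-pad the shorter dimension symmetrically to
   a square (odd remainder goes bottom/right), resize to 224×224, divide
   by 255. Padding *before* the final resize is what preserves the aspect
   ratio.

Coordinates are 0-based, half-open. On phantoms, detected column intervals
reach Jaccard ≥ 0.8 against generator truth on ≥ 95% of knees (asserted at
200 knees).

## Splitting and augmentation

Both knees of a patient are correlated, so the 80/20 train/test split is by
patient (`ceil(0.2·n)` test patients — 301 patients give exactly 61), with
optional stratification by each patient's maximum grade (largest-remainder
allocation; falls back to unstratified with a warning when a stratum has
fewer than two patients).

Training slices are augmented with independent draws of rotation U(±30°),
isotropic zoom U(0.8, 1.2), translation U(±10%) per axis, shear U(±20°),
and a horizontal flip with p = 0.5 — bilinear resampling, zero fill,
clipped to [0, 1]. Each original contributes `copies_per_image` (default 5)
augmented variants; the pooled result is split 90/10 into train/validation
at the slice level. That protocol lets augmented siblings of one slice
appear on both sides of the train/val boundary — deliberate, because it is
the common augment-then-split protocol this package mirrors; the test set
is held out *before* augmentation and never augmented. A stricter
patient-level validation split can be had by applying `patient_split`
twice.

## Classifier

Input 224×224×1 → 3×3 conv to 3 channels (stride 1, same padding, 30
parameters) + ReLU → DenseNet-121 → flatten (7·7·1024 = 50 176) →
FC 128 → FC 64 → FC 16 (each ReLU, L2 λ = 1e-4, dropout 0.3) → FC 5 +
softmax. The DenseNet-121 is the canonical architecture (7×7/2 stem of 64
channels, blocks of 6/12/24/16 bottleneck layers, growth 32, 1×1
bottlenecks at 4× growth, 0.5-compression transitions, BN throughout) and
is fully trainable — no frozen layers. Pretrained weights are an optional
runtime concern; nothing here requires a download.

Parameter accounting books batch-norm scale/shift as trainable and running
mean/variance as non-trainable, the convention under which the backbone
counts 7 037 504 total with 83 648 non-trainable and the whole model
13 469 571 = 13 385 923 + 83 648. These identities are derived from the
instantiated arrays by a generic counter, never hard-coded.

Because no deep-learning framework is part of this package's dependency
set, the network runs on an in-package NumPy layer engine (NHWC): conv2d
(`y_{ij} = ΣΣ X_{i+m,j+n} W_{mn} + b`, implemented as one matmul per kernel
offset), batch norm, ReLU, max/avg pooling, dense, dropout, fused
softmax/cross-entropy, and Adam. All backward passes are hand-derived and
verified against central finite differences (relative error < 1e-3 for the
conv stage on an 8×8 input; most layers pass at < 1e-5).

A `tiny` backbone (2× average-pool input downsample, then three BN-conv
stages to a 7×7×32 feature map) is registered for CPU-scale experiments;
the 2× downsample is chosen so the 1-px grade-4 joint gap remains
resolvable. Batch-norm momentum defaults to 0.9 so running statistics
converge within a few hundred steps of CPU-scale training.

## Training and evaluation

`train` minimizes mean categorical cross-entropy (natural log, probabilities
clipped at 1e-7) with Adam (default lr 1e-4, batch 16), a reduce-on-plateau
schedule (×0.5, patience 3) and early stopping (patience 10) on validation
loss, restoring the best epoch's weights. A non-finite loss aborts with the
epoch index. Per-epoch traces of loss/accuracy/AUC/precision/recall are
kept for both phases.

Metrics: categorical accuracy (argmax match, ties to the lowest class);
one-vs-rest AUC per class by the Mann–Whitney rank statistic with
half-credit ties (equivalent to trapezoidal ROC integration),
macro-averaged over classes present with both positives and negatives;
macro precision TP/(TP+FP) and recall TP/(TP+FN) over classes present in
the truth, zero-denominator classes scored 0 with a warning. Macro
averaging is the package default (micro available for AUC); true
specificity TN/(TN+FP) is reported separately from precision, since the
two are sometimes conflated.

Classical baselines (decision tree with entropy criterion; SVM with C = 0.5,
RBF kernel, one-vs-one decisions; random forest with entropy criterion and
500 trees) operate on flattened 50 176-dim slice vectors standardized
feature-wise, without augmentation by default.

## The desk-scale study

`trainer.desk_scale_study` is the package's reference experiment: 120
uniform-mix phantom patients, patient-level 80/20 split, 2 augmented copies
per training slice, the tiny backbone trained at lr 1e-3 for up to 45
epochs with early stopping, plus a dedicated balanced grade-0/1 probe
cohort of 100 patients (200 knees). It measures

- macro recall over grades 2–4 on the held-out test set — expected ≥ 0.8,
  because those grades differ by construction (gap and osteophyte count);
- grade-0-vs-1 AUC on the probe set, scored as p₁/(p₀+p₁) — expected in
  [0.4, 0.6]; at 200 probe knees the null AUC has SD ≈ 0.04, so that band
  is roughly ±2.4 SD.

Problem sizes were fixed once as the smallest that keep the chance band
tight and the grades learnable on a single CPU in a few minutes; the same
study backs both the acceptance test and `scripts/acceptance.py`.

## Known limitations

- Phantom realism is deliberately minimal (see above); absolute accuracies
  on phantoms say nothing about clinical performance.
- Full DenseNet-121 training on CPU is supported by the engine but slow;
  the tiny backbone is the practical training profile here.
- The slice-level validation split inherits the augment-then-split leakage
  caveat by design; use patient-level validation for honest model
  selection on real data.
- Class rebalancing (weighted loss, oversampling) is out of scope.
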