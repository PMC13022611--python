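# Methods

This note documents the models, parameters and design decisions behind
`wsimil`, and what its synthetic-cohort experiments do and do not show.

## Problem setting

A digitized glass slide carries several physical tissue sections; each
section scan is labeled by a pathologist as normal or abnormal, and
abnormal sections additionally as containing active inflammation and/or
chronic changes/architectural distortion (the phenotypes are not
mutually exclusive). Granuloma status is recorded in the manifest
schema but never modeled: it is far too rare for a stable binary model.
Labels exist only at the section level — no patch is ever annotated —
which makes this a multiple-instance learning (MIL) problem: the scan
is a bag, its retained patches are instances, and a positive bag is
assumed to contain at least one positive instance.

## Tiling geometry

Patches of `patch_size` pixels are laid on the lattice
`0, stride, 2·stride, …` per axis with
`stride = round(patch_size · (1 − overlap))`; defaults are 4096 px and
25% overlap (stride 3072). The per-axis tile count is 1 when the scan
fits in one patch, else `ceil((extent − patch_size)/stride) + 1`; the
trailing tile is zero-padded. Coordinates are 0-based, half-open, in
row-major order. Scans smaller than a patch yield exactly one padded
tile — no section is ever discarded for being small. Under this
convention a 28,416 × 28,928 px scan (a realistic median section size
at 40× magnification) yields a 9 × 10 = 90-patch grid.

The overlap convention at the trailing edge is a genuine choice: we add
origins until the last tile covers the boundary and absorb the
shortfall as zero padding, rather than shifting the last origin to
`extent − patch_size`. This keeps the lattice uniform and makes patch
provenance trivially invertible.

Padding is applied before the bilinear resize to the CNN input size,
and the padding footprint is carried through the resize (interpolated
mask thresholded at 0.5) so QC can distinguish zero fill from genuinely
dark tissue.

## Quality control

Two stages, in a fixed order:

1. **Artifact/background CNN.** Plain intensity thresholds fail on
   patches dominated by pen marks or air bubbles (artifacts can be
   darker than tissue, or brighter than background). A reduced-width
   copy of the patch-classifier architecture (filters 8/16/32/64) is
   trained to reject artifact- or background-dominated patches. In the
   synthetic setting its labels come from the ground-truth masks:
   reject when artifact coverage > 25% or tissue coverage < 5%, usable
   when artifact coverage < 2% and tissue ≥ 25%; ambiguous patches are
   excluded from training.
2. **Otsu tissue rule.** One Otsu threshold (256-bin histogram) is
   computed per scan on a grayscale downsample — per-patch Otsu is
   unstable on homogeneous all-tissue or all-background patches — and a
   patch's tissue fraction is the share of its non-padded pixels darker
   than that threshold (H&E tissue is darker than the slide
   background). Patches with strictly less than 20% tissue are
   rejected; a fully padded patch has fraction 0 by definition.

`qc_status` is a partition: every patch is exactly one of `retained`,
`artifact_rejected`, `low_tissue_rejected`. There is no manual curation
stage anywhere in the pipeline.

## Patch classifier

Three binary models share one architecture: four convolutional sets —
3×3 "same" convolution, ELU, batch normalization (after the
activation), 2×2 max pooling with stride 2, dropout — with filters
16/32/64/128 and dropout 0.10/0.15/0.20/0.25, an L1 kernel penalty of
1e-4 on every convolution, then global max pooling, a 256-unit dense
layer, dropout 0.3 and a single sigmoid output. Optimization is Adam at
learning rate 1e-4 with binary cross entropy, batch size 4, at most 300
epochs, early stopping at patience 50, and the weights of the epoch
with the highest validation accuracy are kept. Inputs are uint8 RGB
scaled to [0, 1] by division by 255; no stain normalization and no
augmentation are applied. Validation accuracy for checkpointing is
computed at the patch level (against the weak labels), since model
selection happens inside the training loop before any aggregation.

Choices the architecture description leaves open, fixed here:
convolution padding is "same" and the pool window is 2×2, so four
halvings take a 128-px input to an 8×8 final map; the hidden dense
layer uses an ELU nonlinearity; class imbalance is left untouched (no
weighting or oversampling).

The network runs on `wsimil.nn`, a compact NumPy CNN engine (NHWC
tensors, convolutions as k² shifted-view GEMMs, explicit backward
passes, Keras-style Adam and batch-norm defaults: eps 1e-3, momentum
0.99, Adam eps 1e-7). All randomness flows through seeded
`numpy.random.Generator`s, so initialization, dropout and shuffling —
hence whole training runs — are bit-reproducible on one platform. The
engine's analytic gradients are verified against central finite
differences in the test suite.

`bn_momentum` is exposed because short desk-scale schedules take only a
few hundred optimizer steps: with the standard 0.99 momentum the
running statistics never catch up with the batch statistics and
inference-mode accuracy collapses. Desk configurations use 0.9.

### Grad-CAM

Gradients of the output logit are taken at a chosen conv set's pooled
activation map via the engine's own backward pass, spatially averaged
into per-channel weights, combined, rectified, bilinearly upsampled to
the patch and max-normalized (normalization after upsampling, so the
displayed maximum is exactly 1). An all-zero map is returned when every
channel contribution is non-positive.

## Aggregation

A patch counts as positive when `p > 0.5`, strictly; a section is
called positive when the positive-patch fraction strictly exceeds 0.5.
Ties therefore go negative at both levels. Only retained patches vote.
The conservative majority rule (rather than "any positive patch")
counters the systematic optimism of weak labels: training marks every
patch of an abnormal section positive even though most contain no
abnormal tissue. Sections whose every patch was rejected are reported
as "no-call", never forced negative.

ROC analysis needs a continuous score on top of the binary rule; the
default is the positive-patch fraction itself (so the call is exactly a
threshold on the score), with mean patch probability as an alternative.

## Evaluation

Patients are the unit of splitting. `make_cv_splits` shuffles patients
under the experiment seed, partitions them into k test groups, and
draws the validation patients from each fold's remainder; with 25
patients and the default layout each fold has 5 test, 3 validation and
17 training patients. Split hygiene (disjoint cohorts, exact test
partition) is asserted at run time, so each test section is scored
exactly once per experiment.

Metrics per fold: accuracy, balanced accuracy, precision, sensitivity,
specificity, F1, MCC, and AUC-ROC computed by the Mann-Whitney rank
statistic with midrank tie handling — important because the
positive-fraction score is coarse and heavily tied. Cross-fold
summaries are mean and *population* SD over the folds. Degenerate folds
(one-class truth) yield `None` for the affected metrics and are
excluded from the mean with an explicit count. MCC for two-class truth
but one-class predictions is 0 by the usual chance convention. The
phenotype models are evaluated on **all** test sections: normal
sections and abnormal sections lacking the phenotype both count as
negatives.

Cohen's κ uses `(po − pe)/(1 − pe)` with `pe` from the raters' marginal
frequencies and a large-sample CI, `κ ± 1.96·sqrt(po(1−po)/(n(1−pe)²))`
clipped to [−1, 1]; when `pe = 1`, κ is 1 for perfect agreement and
undefined otherwise.

The metric implementations are cross-checked in the tests against
scikit-learn (`matthews_corrcoef`, `roc_auc_score`,
`cohen_kappa_score`) and against first-principles oracles (Pearson
correlation of indicator vectors; brute-force between-class-variance
maximization for Otsu).

## Synthetic cohorts

The generator emulates the *structural* features the pipeline depends
on, not histology itself: a near-white background (level 242), 3
elliptical tissue blobs in a pink H&E-like base color with
low-frequency mottling, and, in abnormal sections, one contiguous
witness region grown from a random tissue seed to cover
`witness_fraction` (default 0.6) of the tissue. Phenotype textures
differ so the three models must learn different signals: dense dark
purple spots for active inflammation, oriented dark ridges for chronic
changes, coarse blotches for abnormal sections with neither phenotype.
Artifacts are saturated pen strokes and bright bubble rings covering
`artifact_density` (default 1.5%) of the image. Pixel noise is Gaussian
(SD 4). Every scan is a pure function of (seed, patient id, scan id),
so cohorts are bit-reproducible and streamable.

Cohort-level defaults mirror a realistic section-label regime: 41.2%
abnormal sections, with active inflammation in 87.3% and chronic
changes in 79.5% of abnormal sections (independently drawn, so a small
fraction of abnormal sections carries neither phenotype). The default
witness fraction of 0.6 makes truly abnormal scans satisfiable under
the strict >50% aggregation rule; lowering it below ~0.5 makes the
majority rule — by design — refuse to call sections whose abnormality
is too focal.

What passing these experiments shows: the geometry, QC logic, weak
-label training loop, aggregation rule and patient-level evaluation are
wired correctly and leak-free (the zero-signal control stays at
chance). What it does not show: performance on real H&E, where stain
variation, texture overlap between classes, focal lesions far smaller
than 60% of tissue, and scanner artifacts make the task much harder.
The synthetic textures are nearly separable by construction, so
near-perfect synthetic accuracy is expected and says nothing about
clinical accuracy.

## Problem sizes

Desk-scale experiments use 25 patients × 4 scans (100 scans) at
1024-1536 px per side, 256-px patches (stride 192) resized to 32 px, a
reduced-width CNN (filters 8/16/32/64, dense 64), Adam at 1e-3, batch
32, 8 epochs (2 for the null control, which only needs to demonstrate
chance-level behavior), 5-fold patient-level CV. These sizes were
chosen so a complete three-task, five-fold experiment plus the null
control runs in minutes on a single CPU while keeping ≥20 sections per
test fold. The full-scale defaults (4096-px patches, 128-px inputs,
filters 16/32/64/128, lr 1e-4, batch 4, 300 epochs) are the package's
defaults everywhere and can be used unchanged on real scan archives
with a deep-learning-scale compute budget.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; it is meant for
  small inputs and reduced widths, not 128-px/full-width training runs
  at archive scale.
* Otsu-based tissue fractions count any sufficiently dark pixel as
  tissue; dark artifacts that survive the artifact CNN inflate the
  tissue fraction.
* The section-level ROC score (positive-patch fraction) is coarse:
  AUC estimates on small test folds are step-like and should be read
  together with their SDs.
* Bags with zero retained patches are excluded from training and
  reported as no-calls; downstream prevalence estimates must account
  for them.
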