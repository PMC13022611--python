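# wsimil

Weakly supervised classification of histopathology **tissue-section
scans** — the workflow used to flag abnormal gut biopsy sections in
pediatric inflammatory bowel disease (IBD) and to call two histologic
phenotypes, **active inflammation** and **chronic changes /
architectural distortion**, without any patch-level annotation.

It is aimed at computational-pathology researchers and engineers who
want a complete, inspectable, CPU-scale implementation of the
tile → QC → CNN → multiple-instance-aggregation pattern, including a
seeded synthetic-cohort generator so every stage can be validated
against known ground truth without access to patient data.

## The method

1. **Tiling.** A section scan (often tens of thousands of pixels per
   side) is subdivided into `P × P` patches with 25% overlap along both
   axes (origin lattice `0, s, 2s, …` with stride `s = 0.75 P`;
   defaults `P = 4096`, `s = 3072`). Trailing tiles are zero-padded so
   every scan pixel is covered, and each patch is bilinearly resized to
   the CNN input size (default 128 × 128 × 3).
2. **QC.** A small CNN rejects patches dominated by pen-mark/air-bubble
   artifacts or bare slide background; then one Otsu threshold per scan
   defines "tissue" (pixels darker than the slide background), and
   patches with **less than 20% tissue** (strict) are rejected.
3. **Weakly supervised training (MIL).** Patches inherit their
   section's pathologist label. Three independent binary CNNs are
   trained (abnormal; active inflammation; chronic changes), each with
   four convolutional sets (3×3 conv → ELU → batch norm → 2×2 max pool
   → dropout; filters 16/32/64/128, dropout 0.10/0.15/0.20/0.25, L1
   kernel penalty 1e-4), global max pooling, a 256-unit dense layer
   with dropout 0.3 and a sigmoid output; Adam (lr 1e-4), binary cross
   entropy, batch size 4, ≤300 epochs with early stopping (patience
   50), keeping the best-validation-accuracy weights. The network is
   implemented on a compact NumPy engine with explicit forward/backward
   passes (`wsimil.nn`).
4. **Aggregation.** A patch is positive when its probability `p > 0.5`
   (strict); a section is called positive when **more than 50%** of its
   retained patches are positive — a deliberately conservative rule,
   because weak labels mark *every* patch of an abnormal section as
   abnormal although most contain no abnormal tissue. The
   positive-patch fraction doubles as the continuous section score for
   ROC analysis.
5. **Evaluation.** Patient-level k-fold cross-validation (no patient in
   two cohorts of a fold; test groups partition patients), the full
   binary metric suite per fold (accuracy, balanced accuracy,
   precision, sensitivity, specificity, F1, MCC, rank-based AUC-ROC)
   summarized as mean (SD), plus Cohen's κ with a 95% CI for
   interobserver agreement.

Grad-CAM heatmaps (`wsimil.classifier.gradcam`) localize the image
regions driving a patch prediction.

## Worked example

Everything below runs on synthetic cohorts: H&E-like sections (bright
background, darker textured tissue blobs, a contiguous "witness" region
of abnormal texture in abnormal sections, pen/bubble artifacts) with
pixel-level ground-truth masks.

```python
from wsimil import experiments

reports, manifest = experiments.cv_experiment(seed=1)
for task, rep in reports.items():
    print(f"{task:22s} accuracy {rep.mean['accuracy']:.3f} ({rep.sd['accuracy']:.3f})"
          f"  MCC {rep.mean['mcc']:.3f}  AUC {rep.mean['auc_roc']:.3f}")
```

prints (25 patients, 100 scans, 5-fold patient-level CV, desk-scale
geometry — 256-px patches resized to 32, reduced-width CNN):

```
abnormal               accuracy 0.990 (0.020)  MCC 0.981  AUC 1.000
active_inflammation    accuracy 0.960 (0.037)  MCC 0.918  AUC 0.989
chronic_changes        accuracy 0.980 (0.024)  MCC 0.953  AUC 0.998
```

i.e. with a clean, separable-by-construction cohort the pipeline
recovers the section labels almost perfectly; the same experiment on a
zero-signal cohort (labels independent of the pixels) stays at chance
(MCC ≈ 0), which rules out leakage through the patient-level splits.

The same workflow is available from the shell:

```bash
wsimil synth --out scratch/cohort --seed 1 --n-patients 8 --scans-per-patient 2
wsimil run --config examples/pipeline.yaml --seed 1
```

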