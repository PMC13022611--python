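"""Patient-level cross-validation and the section-level metric suite.

Patients — not scans — are the unit of splitting: every scan of a
patient lands in exactly one of the train/validation/test cohorts of a
fold, the test groups partition the patients across folds, and each test
section is therefore scored exactly once per experiment.  Per fold the
full binary metric set is reported (accuracy, balanced accuracy,
precision, sensitivity, specificity, F1, MCC, rank-based AUC-ROC) and
summarized as mean with population SD across folds.  Degenerate folds
(one-class truth) yield ``None`` for the affected metrics and are
excluded from the mean with an explicit count, never silently zeroed.

Cohen's kappa with a large-sample 95% CI covers interobserver agreement
between two pathologists' section labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import classifier as clf
from . import mil

METRICS = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "mcc",
    "auc_roc",
)


@dataclass(frozen=True)
class CVSplit:
    fold_index: int  # 1-based
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    test_patients: tuple[str, ...]


@dataclass
class FoldReport:
    task: str
    fold_index: int
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict
    n_sections: int
    n_no_call: int = 0


@dataclass
class CVReport:
    task: str
    folds: list[FoldReport]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None  # every test section, scored once

    def summarize(self) -> None:
        """Mean and population SD per metric over folds where it is defined."""
        for m in METRICS:
            vals = [f.metrics[m] for f in self.folds if f.metrics[m] is not None]
            self.n_undefined[m] = len(self.folds) - len(vals)
            if vals:
                self.mean[m] = float(np.mean(vals))
                self.sd[m] = float(np.std(vals))  # population SD over folds
            else:
                self.mean[m] = None
                self.sd[m] = None


def make_cv_splits(
    patient_ids, n_folds: int = 5, n_val: int = 3, seed: int = 0
) -> list[CVSplit]:
    """Seeded patient-wise folds: test groups partition the patients.

    With 25 patients and the defaults each fold has 5 test, 3 validation
    and 17 training patients.
    """
    patients = [str(p) for p in patient_ids]
    if len(set(patients)) != len(patients):
        raise ValueError("patient ids must be unique")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    min_test = len(patients) // n_folds
    if min_test < 1 or len(patients) - (min_test + n_folds - 1) - n_val < 1:
        raise ValueError(
            f"{len(patients)} patients cannot support {n_folds} folds with {n_val} validation patients"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6376]))
    order = list(rng.permutation(patients))
    test_groups = [list(g) for g in np.array_split(np.array(order), n_folds)]
    splits = []
    for k, test in enumerate(test_groups, start=1):
        pool = [p for p in order if p not in test]
        fold_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6376, k]))
        pool = list(fold_rng.permutation(pool))
        val, train = pool[:n_val], pool[n_val:]
        splits.append(CVSplit(k, tuple(train), tuple(val), tuple(test)))
    return splits


def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for binary vectors."""
    t = np.asarray(y_true).ravel().astype(bool)
    p = np.asarray(y_pred).ravel().astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    return tp, fp, tn, fn


def auc_rank(y_true, scores) -> float | None:
    """AUC-ROC via the Mann-Whitney rank statistic with midrank ties."""
    t = np.asarray(y_true).ravel().astype(bool)
    s = np.asarray(scores, dtype=np.float64).ravel()
    n1 = int(t.sum())
    n0 = t.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(s, method="average")
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def mcc_from_confusion(tp: int, fp: int, tn: int, fn: int) -> float | None:
    """Matthews correlation coefficient; None for one-class truth, 0 for
    one-class predictions against two-class truth (chance convention)."""
    if tp + fn == 0 or tn + fp == 0:
        return None
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def compute_metrics(
    conf: tuple[int, int, int, int],
    scores=None,
    y_true=None,
) -> dict:
    """The full metric dictionary from confusion counts (+ scores for AUC)."""
    tp, fp, tn, fn = conf
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    out = {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2 if sens is not None and spec is not None else None,
        "precision": tp / (tp + fp) if tp + fp > 0 else None,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None,
        "mcc": mcc_from_confusion(tp, fp, tn, fn),
        "auc_roc": auc_rank(y_true, scores) if scores is not None and y_true is not None else None,
    }
    return out


@dataclass
class KappaResult:
    kappa: float | None
    ci95: tuple[float, float] | None
    n_items: int


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Chance-corrected agreement between two raters with a 95% CI.

    kappa = (po - pe) / (1 - pe) with pe from the raters' marginal label
    frequencies; the CI uses the large-sample standard error
    sqrt(po (1 - po) / (n (1 - pe)^2)) with normal quantiles.  When
    pe = 1 (both raters constant and identical category sets), kappa is 1
    if agreement is perfect, otherwise undefined.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("rater label vectors differ in length")
    n = a.size
    if n == 0:
        raise ValueError("no items to compare")
    po = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(pa @ pb)
    if pe >= 1.0:
        return KappaResult(1.0 if po == 1.0 else None, None, n)
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    lo = max(-1.0, kappa - 1.959963984540054 * se)
    hi = min(1.0, kappa + 1.959963984540054 * se)
    return KappaResult(float(kappa), (float(lo), float(hi)), n)


def _fold_report(
    task: str,
    fold_index: int,
    preds: list[mil.SectionPrediction],
    manifest: pd.DataFrame,
    n_no_call: int,
) -> FoldReport:
    truth_map = manifest.set_index("scan_id")[task]
    y_true = np.array([int(truth_map.loc[p.scan_id]) for p in preds])
    y_pred = np.array([p.call for p in preds])
    scores = np.array([p.score for p in preds])
    conf = confusion(y_true, y_pred)
    metrics = compute_metrics(conf, scores=scores, y_true=y_true)
    tp, fp, tn, fn = conf
    return FoldReport(task, fold_index, tp, fp, tn, fn, metrics, len(preds), n_no_call)


def cross_validate(
    patches,
    manifest: pd.DataFrame,
    tasks=mil.TASKS,
    cnn_config: clf.CNNConfig | None = None,
    agg_config: mil.AggregationConfig = mil.AggregationConfig(),
    n_folds: int = 5,
    n_val: int = 3,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Patient-level k-fold cross-validation of the full MIL pipeline.

    ``patches`` are QC'd :class:`~wsimil.tiling.PatchRecord` objects for
    the whole cohort; one model per task per fold is trained on the weak
    bag labels, test sections are aggregated with the majority rule, and
    per-fold metric reports are summarized as mean (population SD).
    """
    if cnn_config is None:
        cnn_config = clf.CNNConfig()
    patient_ids = list(pd.unique(manifest["patient_id"]))
    splits = make_cv_splits(patient_ids, n_folds=n_folds, n_val=n_val, seed=seed)
    _assert_split_hygiene(splits, patient_ids)

    reports = {task: CVReport(task, []) for task in tasks}
    for split in splits:
        for t_idx, task in enumerate(tasks):
            bags, empty_bags = mil.build_bags(manifest, patches, task)
            by_cohort = {"train": [], "val": [], "test": []}
            for bag in bags:
                if bag.patient_id in split.test_patients:
                    by_cohort["test"].append(bag)
                elif bag.patient_id in split.val_patients:
                    by_cohort["val"].append(bag)
                else:
                    by_cohort["train"].append(bag)
            x_tr, y_tr = mil.bag_training_arrays(by_cohort["train"])
            x_va, y_va = mil.bag_training_arrays(by_cohort["val"])
            fold_cfg = dataclasses.replace(
                cnn_config, seed=int(np.random.SeedSequence([seed, split.fold_index, t_idx]).generate_state(1)[0] % (2**31))
            )
            model = clf.build_model(fold_cfg)
            trained = clf.train(model, x_tr, y_tr, x_va, y_va, fold_cfg, task=task)
            preds = []
            for bag in by_cohort["test"]:
                probs = clf.predict_patches(trained, np.stack([r.pixels for r in bag.instances]))
                preds.append(mil.aggregate_section(probs, agg_config, scan_id=bag.scan_id))
            n_no_call = sum(b.patient_id in split.test_patients for b in empty_bags)
            reports[task].folds.append(
                _fold_report(task, split.fold_index, preds, manifest, n_no_call=n_no_call)
            )
            frame = mil.predictions_frame(preds, manifest, task)
            frame.insert(1, "fold", split.fold_index)
            reports[task].predictions = (
                frame
                if reports[task].predictions is None
                else pd.concat([reports[task].predictions, frame], ignore_index=True)
            )
    for rep in reports.values():
        rep.summarize()
    return reports


def _assert_split_hygiene(splits: list[CVSplit], patient_ids) -> None:
    all_test: list[str] = []
    for s in splits:
        cohorts = (set(s.train_patients), set(s.val_patients), set(s.test_patients))
        if cohorts[0] & cohorts[1] or cohorts[0] & cohorts[2] or cohorts[1] & cohorts[2]:
            raise AssertionError(f"fold {s.fold_index}: patient appears in two cohorts")
        all_test.extend(s.test_patients)
    if sorted(all_test) != sorted(str(p) for p in patient_ids):
        raise AssertionError("test groups do not partition the patients")


def report_frame(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Mean (SD) summary table, one row per metric, one column pair per task."""
    rows = []
    for m in METRICS:
        row: dict = {"metric": m}
        for task, rep in reports.items():
            row[f"{task}_mean"] = rep.mean.get(m)
            row[f"{task}_sd"] = rep.sd.get(m)
        rows.append(row)
    return pd.DataFrame(rows)
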