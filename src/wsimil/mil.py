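"""Weak-label bags and patch-to-section aggregation.

Sections are labeled by a pathologist; individual patches are not.  Each
scan's retained patches form a bag that inherits the section label for
the task being trained (weak supervision).  At inference a patch counts
as positive when its predicted probability exceeds 0.5 (strict), and the
section is called positive when more than 50% (strict) of its retained
patches are positive — the deliberately conservative threshold that
counters the bias of training every patch of an abnormal section as
abnormal when most of them show no abnormal tissue.

ROC analysis needs a continuous section score on top of the binary rule;
the default score is the positive-patch fraction itself, so the binary
call is exactly a threshold on the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tiling import PatchRecord

TASKS = ("abnormal", "active_inflammation", "chronic_changes")


@dataclass(frozen=True)
class AggregationConfig:
    patch_threshold: float = 0.5  # patch positive iff p > this (strict)
    bag_threshold: float = 0.5  # section positive iff positive fraction > this (strict)
    score_mode: str = "positive_fraction"  # or "mean_probability"

    def __post_init__(self) -> None:
        for name in ("patch_threshold", "bag_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.score_mode not in ("positive_fraction", "mean_probability"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")


@dataclass
class Bag:
    """One scan's retained patches plus its weak (section-level) label."""

    scan_id: str
    patient_id: str
    instances: list[PatchRecord]
    weak_label: int
    task: str


@dataclass
class SectionPrediction:
    scan_id: str
    instance_probs: np.ndarray
    positive_fraction: float
    call: int
    score: float


def build_bags(
    manifest: pd.DataFrame,
    patches: list[PatchRecord],
    task: str,
) -> tuple[list[Bag], list[Bag]]:
    """Group retained patches into one bag per scan for one task.

    Returns (bags, empty_bags): scans whose every patch was rejected get a
    zero-instance bag reported separately — they cannot be trained on or
    called, but are never silently dropped.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    rows = manifest.set_index("scan_id")
    by_scan: dict[str, list[PatchRecord]] = {sid: [] for sid in rows.index}
    for rec in patches:
        if rec.scan_id not in by_scan:
            raise ValueError(f"patch references scan {rec.scan_id!r} absent from manifest")
        if rec.qc_status == "retained":
            by_scan[rec.scan_id].append(rec)
    bags, empty = [], []
    for sid, insts in by_scan.items():
        row = rows.loc[sid]
        bag = Bag(
            scan_id=sid,
            patient_id=str(row["patient_id"]),
            instances=insts,
            weak_label=int(row[task]),
            task=task,
        )
        (bags if insts else empty).append(bag)
    return bags, empty


def section_score(probs: np.ndarray, config: AggregationConfig = AggregationConfig()) -> float:
    """Continuous section score in [0, 1] used for ROC curves."""
    p = np.asarray(probs, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("cannot score a section with no retained patches")
    if config.score_mode == "mean_probability":
        return float(p.mean())
    return float(np.mean(p > config.patch_threshold))


def aggregate_section(
    probs: np.ndarray,
    config: AggregationConfig = AggregationConfig(),
    scan_id: str = "",
) -> SectionPrediction:
    """Apply the majority rule: positive iff >50% of patches have p > 0.5."""
    p = np.asarray(probs, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("cannot aggregate a section with no retained patches")
    positive_fraction = float(np.mean(p > config.patch_threshold))
    call = int(positive_fraction > config.bag_threshold)
    return SectionPrediction(
        scan_id=scan_id,
        instance_probs=p,
        positive_fraction=positive_fraction,
        call=call,
        score=section_score(p, config),
    )


def bag_training_arrays(bags: list[Bag]) -> tuple[np.ndarray, np.ndarray]:
    """Flatten bags into (pixels, weak labels) for patch-level training."""
    pixels = [rec.pixels for bag in bags for rec in bag.instances]
    labels = [bag.weak_label for bag in bags for _ in bag.instances]
    if not pixels:
        return np.zeros((0, 1, 1, 3), np.uint8), np.zeros(0, np.int64)
    return np.stack(pixels), np.asarray(labels, dtype=np.int64)


def predictions_frame(
    predictions: list[SectionPrediction],
    manifest: pd.DataFrame,
    task: str,
) -> pd.DataFrame:
    """Section predictions as the standard CSV schema."""
    truth = manifest.set_index("scan_id")[task]
    return pd.DataFrame(
        {
            "scan_id": [p.scan_id for p in predictions],
            "task": task,
            "n_patches": [len(p.instance_probs) for p in predictions],
            "positive_fraction": [p.positive_fraction for p in predictions],
            "score": [p.score for p in predictions],
            "call": [p.call for p in predictions],
            "true_label": [int(truth.loc[p.scan_id]) for p in predictions],
        }
    )
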