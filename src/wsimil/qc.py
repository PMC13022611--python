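"""Two-stage patch quality control.

Stage 1 is a small CNN that rejects patches dominated by pen-mark /
air-bubble artifacts or bare slide background — failure modes that
defeat plain intensity thresholding.  Stage 2 applies Otsu's method:
one grayscale threshold is computed per scan (padding excluded), each
surviving patch's tissue fraction is the share of its non-padded pixels
darker than that threshold, and patches with less than 20% tissue
(strict inequality) are rejected.  The stage order is fixed: CNN first,
then the tissue rule.

``qc_status`` is a partition — every patch ends as exactly one of
``retained``, ``artifact_rejected`` or ``low_tissue_rejected``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from . import classifier as clf
from .tiling import PatchRecord

#: Rec. 709 luma weights, as used by scikit-image's rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class QCConfig:
    artifact_threshold: float = 0.5
    min_tissue_fraction: float = 0.20
    otsu_scope: str = "per_scan"

    def __post_init__(self) -> None:
        for name in ("artifact_threshold", "min_tissue_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.otsu_scope != "per_scan":
            raise ValueError("only per_scan Otsu thresholding is supported")


@dataclass
class QCReport:
    """Per-scan QC bookkeeping; counts always sum to the scan's patch total."""

    counts: dict = field(default_factory=dict)
    artifact_probs: list = field(default_factory=list)
    tissue_fractions: list = field(default_factory=list)
    otsu_threshold: float = float("nan")


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Standard luminance on the 0-255 scale."""
    return np.asarray(pixels, dtype=np.float64) @ _LUMA


def compute_scan_otsu(gray: np.ndarray, valid_mask: np.ndarray | None = None) -> float:
    """Otsu threshold (256-bin histogram) over the valid pixels of one scan.

    A degenerate image with a single gray value returns that value.
    """
    g = np.asarray(gray, dtype=np.float64)
    vals = g[valid_mask] if valid_mask is not None else g.ravel()
    if vals.size == 0:
        raise ValueError("cannot compute an Otsu threshold on an empty image")
    if np.ptp(vals) == 0:
        return float(vals.flat[0])
    return float(threshold_otsu(vals, nbins=256))


def tissue_fraction(patch: PatchRecord, scan_otsu_threshold: float) -> float:
    """Share of non-padded pixels darker than the scan threshold; 0 if all padding."""
    if not (0.0 <= scan_otsu_threshold <= 255.0):
        raise ValueError(f"threshold must be a gray level in [0, 255], got {scan_otsu_threshold}")
    valid = ~patch.pad_mask
    if not valid.any():
        return 0.0
    gray = to_gray(patch.pixels)
    return float(np.mean(gray[valid] < scan_otsu_threshold))


def train_artifact_filter(
    patches: list[PatchRecord] | np.ndarray,
    labels: np.ndarray,
    config: QCConfig = QCConfig(),
    cnn_config: clf.CNNConfig | None = None,
    val_fraction: float = 0.2,
) -> clf.TrainedModel:
    """Train the artifact/background rejection CNN on labeled patches.

    Label 1 marks patches to reject.  The network is the patch-classifier
    architecture at reduced width (filters 8/16/32/64 at full scale); a
    seeded slice of the input is held out as the checkpointing validation
    split.
    """
    pixels = _as_pixel_array(patches)
    y = np.asarray(labels).ravel()
    if len(pixels) == 0:
        raise ValueError("empty artifact-filter training set")
    if len(pixels) != len(y):
        raise ValueError("patches and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("artifact-filter training needs both classes present")
    if cnn_config is None:
        size = pixels.shape[1]
        cnn_config = clf.CNNConfig(
            input_size=size,
            filters=(8, 16, 32, 64),
            learning_rate=1e-3,
            batch_size=32,
            max_epochs=12,
            early_stop_patience=12,
            bn_momentum=0.9,  # short schedule: running stats must catch up
        )
    rng = np.random.default_rng(np.random.SeedSequence([cnn_config.seed, 0x7163]))
    order = rng.permutation(len(pixels))
    n_val = max(1, int(round(val_fraction * len(pixels))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("training split lost a class; provide more labeled patches")
    model = clf.build_model(cnn_config)
    return clf.train(
        model, pixels[tr_idx], y[tr_idx], pixels[val_idx], y[val_idx], cnn_config,
        task="artifact_filter",
    )


def _as_pixel_array(patches) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        return patches
    return np.stack([p.pixels for p in patches]) if patches else np.zeros((0, 1, 1, 3), np.uint8)


def apply_artifact_filter(
    patches: list[PatchRecord],
    model: clf.TrainedModel,
    config: QCConfig = QCConfig(),
) -> list[PatchRecord]:
    """Mark patches with artifact probability above threshold; order preserved."""
    if model is None or not model.history:
        raise RuntimeError("artifact filter model is untrained")
    if not patches:
        return patches
    probs = clf.predict_patches(model, _as_pixel_array(patches))
    for rec, p in zip(patches, probs):
        rec.artifact_prob = float(p)
        if rec.qc_status == "retained" and p > config.artifact_threshold:
            rec.qc_status = "artifact_rejected"
    return patches


def apply_tissue_filter(
    patches: list[PatchRecord],
    scan_otsu_threshold: float,
    config: QCConfig = QCConfig(),
) -> tuple[list[PatchRecord], QCReport]:
    """Reject still-retained patches with tissue fraction below the minimum.

    Runs after the artifact CNN.  Fully padded patches have fraction 0 and
    are rejected whenever ``min_tissue_fraction > 0``.
    """
    report = QCReport(otsu_threshold=float(scan_otsu_threshold))
    for rec in patches:
        frac = tissue_fraction(rec, scan_otsu_threshold)
        rec.tissue_frac = frac
        report.tissue_fractions.append(frac)
        report.artifact_probs.append(rec.artifact_prob)
        if rec.qc_status == "retained" and frac < config.min_tissue_fraction:
            rec.qc_status = "low_tissue_rejected"
    statuses = ("retained", "artifact_rejected", "low_tissue_rejected")
    report.counts = {s: sum(r.qc_status == s for r in patches) for s in statuses}
    return patches, report


def qc_scan(
    patches: list[PatchRecord],
    scan_gray: np.ndarray,
    artifact_model: clf.TrainedModel | None,
    config: QCConfig = QCConfig(),
) -> tuple[list[PatchRecord], QCReport]:
    """Full per-scan QC: artifact CNN first, then the Otsu tissue rule."""
    if artifact_model is not None:
        apply_artifact_filter(patches, artifact_model, config)
    threshold = compute_scan_otsu(scan_gray)
    return apply_tissue_filter(patches, threshold, config)
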