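"""PNG figures: confusion matrices, ROC curves, Grad-CAM overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import auc_rank


def confusion_matrix_png(tp: int, fp: int, tn: int, fn: int, path: str | Path, title: str = "") -> None:
    counts = np.array([[tn, fp], [fn, tp]])
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > counts.max() / 2 else "black")
    ax.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax.set_yticks([0, 1], ["true 0", "true 1"])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_curve_points(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) swept over all score thresholds, highest first."""
    t = np.asarray(y_true).ravel().astype(bool)
    s = np.asarray(scores, dtype=np.float64).ravel()
    order = np.argsort(-s, kind="stable")
    t = t[order]
    tps = np.concatenate([[0], np.cumsum(t)])
    fps = np.concatenate([[0], np.cumsum(~t)])
    n1, n0 = max(t.sum(), 1), max((~t).sum(), 1)
    return fps / n0, tps / n1


def roc_png(y_true, scores, path: str | Path, title: str = "") -> None:
    fpr, tpr = roc_curve_points(y_true, scores)
    auc = auc_rank(y_true, scores)
    fig, ax = plt.subplots(figsize=(3.4, 3.2))
    ax.plot(fpr, tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    label = f"AUC = {auc:.3f}" if auc is not None else "AUC undefined"
    ax.set_title(f"{title} {label}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gradcam_overlay_png(patch: np.ndarray, cam: np.ndarray, path: str | Path, alpha: float = 0.45) -> None:
    fig, ax = plt.subplots(figsize=(3.0, 3.0))
    ax.imshow(patch)
    ax.imshow(cam, cmap="jet", alpha=alpha, vmin=0.0, vmax=1.0)
    ax.set_axis_off()
    fig.tight_layout(pad=0.1)
    fig.savefig(path, dpi=120)
    plt.close(fig)
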