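"""Per-patch CNN classifiers: architecture, training schedule, Grad-CAM.

Three independently trained binary models share one architecture: four
convolutional sets (3x3 conv -> ELU -> batch norm -> 2x2 max pool ->
dropout) with filter counts 16/32/64/128 and dropout 0.1/0.15/0.2/0.25,
an L1 kernel penalty of 1e-4, then global max pooling, a 256-unit dense
layer with dropout 0.3 and a single sigmoid output.  Training uses Adam
(lr 1e-4), binary cross entropy, batch size 4, up to 300 epochs with
early stopping at patience 50, keeping the weights of the epoch with the
best validation accuracy.  Those are the full-scale defaults; width,
input size and schedule are configurable for desk-scale runs.

Inputs are uint8 RGB patches scaled to [0, 1] by division by 255 — no
stain normalization or augmentation is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn

LAYERS_PER_SET = 5  # conv, elu, batchnorm, pool, dropout


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training schedule for one binary patch model."""

    input_size: int = 128
    filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    dropout: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25)
    kernel_l1: float = 1e-4
    dense_units: int = 256
    head_dropout: float = 0.3
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 300
    early_stop_patience: int = 50
    bn_momentum: float = 0.99  # lower it for short schedules with few steps
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != len(self.dropout):
            raise ValueError("filters and dropout must have one entry per conv set")
        if any(f2 <= f1 for f1, f2 in zip(self.filters, self.filters[1:])):
            raise ValueError("filter counts must be strictly increasing")
        if any(not (0.0 <= d < 1.0) for d in (*self.dropout, self.head_dropout)):
            raise ValueError("dropout rates must be in [0, 1)")
        if not (1 <= self.early_stop_patience < self.max_epochs + 1):
            raise ValueError("patience must be in [1, max_epochs]")
        if self.input_size % (2 ** len(self.filters)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{len(self.filters)}"
            )


@dataclass
class TrainedModel:
    """A trained binary patch classifier plus its training history."""

    task: str
    model: nn.Sequential
    config: CNNConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = 0  # 1-based epoch whose weights are loaded


def build_model(config: CNNConfig) -> nn.Sequential:
    """Construct the (untrained) network; same seed gives identical weights."""
    ss = np.random.SeedSequence([int(config.seed), 0x6D6F6465])
    rngs = [np.random.default_rng(c) for c in ss.spawn(2 * len(config.filters) + 4)]
    layers: list[nn.Layer] = []
    in_ch = 3
    r = iter(rngs)
    for f, d in zip(config.filters, config.dropout):
        layers.append(nn.Conv2D(in_ch, f, config.kernel, l1=config.kernel_l1, rng=next(r)))
        layers.append(nn.ELU())
        layers.append(nn.BatchNorm(f, momentum=config.bn_momentum))
        layers.append(nn.MaxPool2())
        layers.append(nn.Dropout(d, rng=next(r)))
        in_ch = f
    layers.append(nn.GlobalMaxPool())
    layers.append(nn.Dense(in_ch, config.dense_units, rng=next(r)))
    layers.append(nn.ELU())
    layers.append(nn.Dropout(config.head_dropout, rng=next(r)))
    layers.append(nn.Dense(config.dense_units, 1, rng=next(r)))
    return nn.Sequential(layers)


def _scale(patches: np.ndarray) -> np.ndarray:
    x = np.asarray(patches)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValueError(f"expected (n, h, w, 3) patch array, got {x.shape}")
    return (x.astype(np.float32) / np.float32(255.0)) if x.dtype != np.float32 else x


def train(
    model: nn.Sequential,
    train_patches: np.ndarray,
    train_labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    config: CNNConfig,
    task: str = "abnormal",
) -> TrainedModel:
    """Fit with Adam/BCE, checkpointing the best-validation-accuracy epoch.

    Stops after ``early_stop_patience`` epochs without a new best
    validation accuracy, or at ``max_epochs``, and restores the best
    weights before returning.
    """
    y_tr = np.asarray(train_labels, dtype=np.float32).ravel()
    y_va = np.asarray(val_labels, dtype=np.float32).ravel()
    if y_tr.size == 0 or y_va.size == 0:
        raise ValueError("training and validation sets must be non-empty")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    x_tr = _scale(train_patches)
    x_va = _scale(val_patches)

    opt = nn.Adam(model, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7368]))
    hist: dict = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_epoch, best_weights = -1.0, 0, model.get_weights()

    n = len(x_tr)
    bs = config.batch_size
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x_tr[idx], y_tr[idx]
            z = model.forward(xb, training=True).ravel()
            p = nn.sigmoid(z)
            losses.append(nn.bce_with_logits(z, yb) * len(idx))
            correct += int(np.sum((p > 0.5) == (yb > 0.5)))
            g = ((p - yb) / len(idx)).astype(np.float32)[:, None]
            model.backward(g)
            opt.step()
        z_va = model.predict_logits(x_va)
        val_acc = float(np.mean((nn.sigmoid(z_va) > 0.5) == (y_va > 0.5)))
        hist["train_loss"].append(float(np.sum(losses) / n))
        hist["train_acc"].append(correct / n)
        hist["val_loss"].append(nn.bce_with_logits(z_va, y_va))
        hist["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = model.get_weights()
        if epoch - best_epoch >= config.early_stop_patience:
            break

    model.set_weights(best_weights)
    return TrainedModel(task=task, model=model, config=config, history=hist, best_epoch=best_epoch)


def predict_patches(trained: TrainedModel, patches: np.ndarray) -> np.ndarray:
    """Per-patch probabilities, order-aligned with the input (dropout off)."""
    if not trained.history:
        raise RuntimeError("model has no training history; train it first")
    if len(patches) == 0:
        return np.zeros(0, dtype=np.float64)
    z = trained.model.predict_logits(_scale(patches))
    return nn.sigmoid(z)


def gradcam(trained: TrainedModel, patch: np.ndarray, conv_set_index: int = 4) -> np.ndarray:
    """Gradient-weighted class-activation map for one patch.

    Gradients of the output logit are taken at the chosen conv set's
    pooled activation map (native size ``input_size / 2**k``), averaged
    spatially into per-channel weights, combined, rectified, max-normalized
    and bilinearly upsampled to the patch size.  An all-zero map is
    returned when every channel contribution is non-positive.
    """
    n_sets = len(trained.config.filters)
    if not (1 <= conv_set_index <= n_sets):
        raise ValueError(f"conv_set_index must be in 1..{n_sets}, got {conv_set_index}")
    if not trained.history:
        raise RuntimeError("model has no training history; train it first")
    x = _scale(patch[None, ...])
    model = trained.model
    model.forward(x, training=False)
    layer_idx = (conv_set_index - 1) * LAYERS_PER_SET + 3  # the set's pool output
    act, grad = model.gradient_at(layer_idx, np.ones((1, 1), dtype=np.float32))
    weights = grad.mean(axis=(0, 1, 2))
    cam = np.maximum(act[0] @ weights, 0.0).astype(np.float64)
    h, w = patch.shape[:2]
    cam = _sk_resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    m = cam.max()
    if m > 0:
        cam /= m
    return cam


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Weights to ``<path>.npz``; config/history/selected epoch to ``<path>.json``."""
    path = Path(path)
    weights = trained.model.get_weights()
    np.savez(path.with_suffix(".npz"), *weights)
    sidecar = {
        "task": trained.task,
        "config": asdict(trained.config),
        "history": trained.history,
        "best_epoch": trained.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_raw = sidecar["config"]
    for k in ("filters", "dropout"):
        cfg_raw[k] = tuple(cfg_raw[k])
    config = CNNConfig(**cfg_raw)
    model = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    return TrainedModel(
        task=sidecar["task"],
        model=model,
        config=config,
        history=sidecar["history"],
        best_epoch=sidecar["best_epoch"],
    )
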