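"""Patch-level classifier: cosine-decay schedules, training, prediction, Grad-CAM.

Transfer-learning style optimization uses two parameter groups.  The task
head follows the cosine decay

    eta(t) = eta_min + 1/2 (eta_max - eta_min) (1 + cos(pi * T_cur / T_i))

while the backbone learning rate is 0 for T_cur <= T_i/2 and equals the
cosine schedule afterwards, i.e. the backbone is frozen for the first half
of training and then fine-tuned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

from .nn import SmallCNN, cross_entropy, softmax

__all__ = [
    "LrSchedule",
    "TrainConfig",
    "task_lr",
    "backbone_lr",
    "train_patch_classifier",
    "predict_likelihoods",
    "prob_columns",
    "gradcam",
    "PatchClassifier",
    "ARCHITECTURES",
]


@dataclass(frozen=True)
class LrSchedule:
    """State of the cosine-decay schedule (eta_min, eta_max, T_i, T_cur)."""

    eta_min: float = 0.0
    eta_max: float = 0.01
    T_i: float = 8.0
    T_cur: float = 0.0

    def validate(self) -> None:
        if self.T_i <= 0:
            raise ValueError("T_i must be > 0")
        if not 0 <= self.eta_min <= self.eta_max:
            raise ValueError("need 0 <= eta_min <= eta_max")
        if not 0 <= self.T_cur <= self.T_i:
            raise ValueError("T_cur must lie in [0, T_i]")


def task_lr(s: LrSchedule) -> float:
    """Cosine-decay learning rate for the task-specific head."""
    s.validate()
    return s.eta_min + 0.5 * (s.eta_max - s.eta_min) * (
        1.0 + math.cos(math.pi * s.T_cur / s.T_i))


def backbone_lr(s: LrSchedule) -> float:
    """Backbone learning rate: frozen for the first half, cosine afterwards."""
    s.validate()
    if s.T_cur <= 0.5 * s.T_i:
        return 0.0
    return task_lr(s)


ARCHITECTURES = {"small_cnn": SmallCNN}


@dataclass(frozen=True)
class TrainConfig:
    """Patch-classifier training configuration.

    ``architecture`` defaults to the desk-scale numpy CNN; "inception_v3"
    (the full-scale choice) requires a deep-learning framework that is not
    part of this environment and raises a clear error if requested.
    ``pretrained`` is kept for interface compatibility: with no framework
    there are no published weights to load, so it only annotates the log.
    """

    architecture: str = "small_cnn"
    input_size: int = 32
    batch_size: int = 128
    epochs: int = 8
    eta_min: float = 0.0
    eta_max: float = 0.01
    momentum: float = 0.9
    pretrained: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture {self.architecture!r} unavailable in this "
                f"environment; choose from {sorted(ARCHITECTURES)}"
            )


class PatchClassifier:
    """A fitted backbone plus its class labels and input conventions."""

    def __init__(self, net: SmallCNN, classes: list[str], input_size: int):
        self.net = net
        self.classes = list(classes)
        self.input_size = input_size

    def preprocess(self, tiles: list[np.ndarray]) -> np.ndarray:
        out = np.empty((len(tiles), self.input_size, self.input_size, 3))
        for i, t in enumerate(tiles):
            a = np.asarray(t, dtype=float)
            if a.dtype != float:
                a = a.astype(float)
            if np.issubdtype(np.asarray(t).dtype, np.integer):
                a = a / 255.0
            if a.shape[0] != self.input_size or a.shape[1] != self.input_size:
                a = resize(a, (self.input_size, self.input_size),
                           anti_aliasing=True)
            if a.shape[-1] != 3:
                raise ValueError(f"tile {i}: expected 3 channels, got {a.shape}")
            out[i] = a
        return out

    def predict_proba(self, tiles: list[np.ndarray]) -> np.ndarray:
        return self.net.predict_proba(self.preprocess(tiles))

    def save(self, path) -> None:
        self.net.save(path)
        import json
        from pathlib import Path
        meta_path = Path(path).with_suffix(".classes.json")
        meta_path.write_text(json.dumps(
            {"classes": self.classes, "input_size": self.input_size}))

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        import json
        from pathlib import Path
        net = SmallCNN.load(path)
        meta = json.loads(Path(path).with_suffix(".classes.json").read_text())
        return cls(net, meta["classes"], meta["input_size"])


def train_patch_classifier(
    tiles: list[np.ndarray],
    labels: list[str],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[PatchClassifier, list[dict]]:
    """Train the patch classifier under the two-group cosine schedule.

    Patch labels are inherited from their slide (weak supervision).  Returns
    the fitted model and a per-epoch log with both learning rates, loss and
    training accuracy.
    """
    cfg.validate()
    if len(tiles) != len(labels):
        raise ValueError("tiles and labels length mismatch")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train, got "
                         f"{classes}")
    y = np.array([classes.index(l) for l in labels])

    net = ARCHITECTURES[cfg.architecture](
        n_classes=len(classes), input_size=cfg.input_size, seed=cfg.seed)
    clf = PatchClassifier(net, classes, cfg.input_size)
    x = clf.preprocess(tiles)
    net.fit_feature_norm(x)

    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    n_batches = max(1, math.ceil(n / cfg.batch_size))
    log: list[dict] = []
    sched = LrSchedule(eta_min=cfg.eta_min, eta_max=cfg.eta_max,
                       T_i=float(cfg.epochs))
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        epoch_sched = replace(sched, T_cur=float(epoch))
        for b in range(n_batches):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            # T_cur advances continuously within the epoch.
            s = replace(sched, T_cur=min(epoch + b / n_batches, sched.T_i))
            logits = net.forward(x[idx])
            probs = softmax(logits)
            loss = cross_entropy(probs, y[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}: {loss}")
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            dlogits /= len(idx)
            net.backward(dlogits)
            net.sgd_step(task_lr(s), backbone_lr(s), momentum=cfg.momentum)
            losses.append(loss)
            correct += int((probs.argmax(1) == y[idx]).sum())
        log.append({
            "epoch": epoch,
            "task_lr": task_lr(epoch_sched),
            "backbone_lr": backbone_lr(epoch_sched),
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
            "pretrained": cfg.pretrained,
        })
    return clf, log


def prob_columns(classes: list[str]) -> list[str]:
    return [f"p_{c}" for c in classes]


def predict_likelihoods(
    model: PatchClassifier,
    tiles: list[np.ndarray],
    keys: pd.DataFrame,
) -> pd.DataFrame:
    """Emit the patch-likelihood table for a batch of kept tiles.

    ``keys`` must carry one row per tile with columns
    ``case_id, slide_id, col, row``.  Output adds ``p_<class>`` simplex
    columns and the argmax ``label`` (ties resolved to the lowest class
    index).  Deterministic given the fitted model.
    """
    required = {"case_id", "slide_id", "col", "row"}
    missing = required - set(keys.columns)
    if missing:
        raise ValueError(f"keys missing columns: {sorted(missing)}")
    if len(keys) != len(tiles):
        raise ValueError("keys and tiles length mismatch")
    for i, t in enumerate(tiles):
        a = np.asarray(t)
        if a.ndim != 3 or a.shape[-1] != 3:
            raise ValueError(f"tile {i}: expected HxWx3, got shape {a.shape}")
    probs = model.predict_proba(tiles)
    out = keys[["case_id", "slide_id", "col", "row"]].reset_index(drop=True).copy()
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = probs[:, j]
    out["label"] = [model.classes[j] for j in probs.argmax(axis=1)]
    return out


def gradcam(model: PatchClassifier, tile: np.ndarray, target_class: str) -> np.ndarray:
    """Grad-CAM heatmap for one tile, upsampled to the tile's size.

    Non-negative, max-normalized to [0, 1]; all-zero when the class gradient
    vanishes.
    """
    if target_class not in model.classes:
        raise ValueError(f"unknown class {target_class!r}")
    x = model.preprocess([tile])[0]
    cam = model.net.gradcam(x, model.classes.index(target_class))
    h, w = np.asarray(tile).shape[:2]
    up = resize(cam, (h, w), order=1, anti_aliasing=False)
    if up.max() > 0:
        up = up / up.max()
    return np.maximum(up, 0.0)
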