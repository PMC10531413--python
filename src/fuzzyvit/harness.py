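"""Training and evaluation harness: stratified 5-fold CV at a 4:1 ratio.

Protocol: the labeled pool is split into five stratified folds; each fold
serves once as the held-out test set while the remaining four train the
model, giving the 4:1 train:test ratio. Per-fold metrics (accuracy,
per-class and macro precision/recall/F1, AUC) are aggregated as
mean +/- sample standard deviation over the five folds.

Optimization is plain SGD with momentum on the cross-entropy of the two
class logits, with a cosine-decayed learning rate. Every random stream
(fold shuffling, weight init, batch order) derives deterministically from
``TrainConfig.seed``, so a full run is bit-reproducible on one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor, softmax
from .encoder import EncoderConfig, FRPETransformer
from .metrics import MetricsReport, confusion, metrics_report, roc_auc
from .phantom import DatasetManifest

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "RunLog",
    "FoldResult",
    "stratified_kfold",
    "load_images",
    "train",
    "train_on_arrays",
    "evaluate_model",
    "cross_validate",
]

_LABEL_TO_INT = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    """Training conditions. Defaults are the desk-scale study conditions.

    ``optimizer`` is "adam" (decoupled weight decay on weight matrices and
    the fuzzy table) or "sgd" (momentum + cosine-decayed lr with global
    gradient-norm clipping). ``augment_flip`` mirrors each training batch
    horizontally with probability 1/2 (label-preserving for the phantoms).
    """

    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.05
    momentum: float = 0.9
    clip_norm: float = 1.0  # sgd only; 0 disables
    warmup_epochs: int = 5
    label_smoothing: float = 0.1
    augment_flip: bool = True
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("epochs/batch_size must be >= 1 and learning_rate >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class FoldResult:
    fold_id: int
    report: MetricsReport
    auc: float

    @property
    def accuracy(self) -> float:
        return self.report.accuracy


@dataclass
class RunLog:
    """Per-epoch training curve plus per-fold and aggregate evaluation."""

    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    folds: list[FoldResult] = field(default_factory=list)

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """mean +/- sample std over folds for each headline metric."""
        if not self.folds:
            return {}
        out = {}
        for name, values in {
            "accuracy": [f.accuracy for f in self.folds],
            "macro_precision": [f.report.macro_precision for f in self.folds],
            "macro_recall": [f.report.macro_recall for f in self.folds],
            "macro_f1": [f.report.macro_f1 for f in self.folds],
            "auc": [f.auc for f in self.folds],
        }.items():
            arr = np.asarray(values)
            std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            out[name] = (float(arr.mean()), std)
        return out

    def format_summary(self) -> str:
        lines = []
        for name, (mean, std) in self.aggregate().items():
            unit = "%" if name != "auc" else ""
            prec = 2 if name != "auc" else 4
            lines.append(f"{name:16s} {mean:.{prec}f} ± {std:.{prec}f}{unit}")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "epoch_loss": self.epoch_loss,
            "epoch_accuracy": self.epoch_accuracy,
            "folds": [
                {"fold": f.fold_id, "auc": f.auc, **f.report.to_dict()} for f in self.folds
            ],
            "aggregate": {k: {"mean": m, "std": s} for k, (m, s) in self.aggregate().items()},
        }
        return json.dumps(payload, indent=2)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic stratified partition into k folds."""
    y = np.asarray([_LABEL_TO_INT.get(l, l) for l in labels], dtype=int)
    counts = np.bincount(y)
    if np.any(counts[counts > 0] < k):
        raise ValueError(f"every class needs at least k={k} members, got counts {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(fold_id=i, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(skf.split(np.zeros_like(y), y))
    ]


def load_images(manifest: DatasetManifest, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest images: grayscale, bilinear resize, per-image min-max.

    Returns (images (N, S, S) float64 in [0,1], labels (N,) int 0=benign).
    """
    images = []
    for path in manifest.paths():
        with Image.open(path) as img:
            img = img.convert("L")
            if img.size != (input_size, input_size):
                img = img.resize((input_size, input_size), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float64)
        lo, hi = arr.min(), arr.max()
        images.append((arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr))
    labels = np.asarray([_LABEL_TO_INT[l] for l in manifest.labels], dtype=int)
    return np.stack(images), labels


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 9973 + salt) % (2**31)


def _decayed(name: str) -> bool:
    # weight matrices and the fuzzy position table; not biases, gains or LN
    return "W" in name or "raw" in name


class _Optimizer:
    """Adam with decoupled weight decay, or clipped SGD with momentum."""

    def __init__(self, params: dict[str, Tensor], cfg: "TrainConfig"):
        self.params = params
        self.cfg = cfg
        self.lr = cfg.learning_rate
        self.step_count = 0
        self.slot1 = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.slot2 = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        cfg = self.cfg
        self.step_count += 1
        if cfg.optimizer == "sgd":
            scale = 1.0
            if cfg.clip_norm > 0:
                sq = sum(
                    float((t.grad**2).sum())
                    for t in self.params.values()
                    if t.grad is not None
                )
                norm = np.sqrt(sq)
                if norm > cfg.clip_norm:
                    scale = cfg.clip_norm / norm
            for name, t in self.params.items():
                if t.grad is None:
                    continue
                v = self.slot1[name]
                v *= cfg.momentum
                v -= self.lr * scale * t.grad
                t.data += v
            return
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, t in self.params.items():
            g = t.grad
            if g is None:
                continue
            m = self.slot1[name]
            v = self.slot2[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.step_count)
            vhat = v / (1 - b2**self.step_count)
            t.data -= self.lr * mhat / (np.sqrt(vhat) + eps)
            if cfg.weight_decay > 0 and _decayed(name):
                t.data -= self.lr * cfg.weight_decay * t.data

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None


def _cross_entropy(logits: Tensor, y: np.ndarray, smoothing: float = 0.0) -> Tensor:
    logp = softmax(logits, axis=-1).log()
    picked = logp[np.arange(len(y)), y]
    if smoothing == 0.0:
        return -(picked.mean())
    # two-class label smoothing: (1-eps) on the true class, eps/2 on each
    uniform = logp.mean(axis=-1)
    return -((1.0 - smoothing) * picked.mean() + smoothing * uniform.mean())


def train_on_arrays(
    images: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> tuple[FRPETransformer, RunLog]:
    """Fit a fresh model on in-memory arrays; returns the model and its log."""
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    model = FRPETransformer(cfg.encoder, seed=_derive_seed(cfg.seed, 1))
    opt = _Optimizer(model.parameters(), cfg)
    shuffle_rng = np.random.default_rng(_derive_seed(cfg.seed, 2))
    log = RunLog()
    n = len(images)
    model.training = True
    for epoch in range(cfg.epochs):
        # linear warmup then cosine decay
        if epoch < cfg.warmup_epochs:
            opt.lr = cfg.learning_rate * (epoch + 1) / cfg.warmup_epochs
        else:
            frac = (epoch - cfg.warmup_epochs) / max(1, cfg.epochs - cfg.warmup_epochs)
            opt.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = images[idx]
            if cfg.augment_flip and shuffle_rng.random() < 0.5:
                batch = np.ascontiguousarray(batch[:, :, ::-1])
            logits = model.forward(batch)
            loss = _cross_entropy(logits, labels[idx], cfg.label_smoothing)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        log.epoch_loss.append(float(np.mean(losses)))
        log.epoch_accuracy.append(100.0 * correct / n)
    model.training = False
    return model, log


def train(manifest: DatasetManifest, cfg: TrainConfig) -> tuple[FRPETransformer, RunLog]:
    """Fit on every image in the manifest (see ``cross_validate`` for CV)."""
    images, labels = load_images(manifest, cfg.encoder.input_size)
    return train_on_arrays(images, labels, cfg)


def evaluate_model(
    model: FRPETransformer,
    images: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 32,
    flip_average: bool = True,
) -> FoldResult:
    """Confusion-matrix report and AUC of a trained model on held-out data.

    With ``flip_average`` the malignancy score is the mean over the image
    and its horizontal mirror (deterministic test-time averaging, matching
    the flip augmentation used in training).
    """

    def batch_scores(batch: np.ndarray) -> np.ndarray:
        s = model.predict_proba(batch)[:, 1]
        if flip_average:
            s = 0.5 * (s + model.predict_proba(np.ascontiguousarray(batch[:, :, ::-1]))[:, 1])
        return s

    scores = np.concatenate(
        [batch_scores(images[i : i + batch_size]) for i in range(0, len(images), batch_size)]
    )
    preds = (scores >= 0.5).astype(int)
    report = metrics_report(confusion(labels, preds))
    auc = roc_auc(labels, scores).auc
    return FoldResult(fold_id=-1, report=report, auc=auc)


def cross_validate(manifest: DatasetManifest, cfg: TrainConfig, k: int = 5) -> RunLog:
    """Stratified k-fold CV; per-fold metrics plus mean +/- std aggregate."""
    images, labels = load_images(manifest, cfg.encoder.input_size)
    folds = stratified_kfold(labels, k=k, seed=cfg.seed)
    out = RunLog()
    for split in folds:
        fold_cfg = replace(cfg, seed=_derive_seed(cfg.seed, 100 + split.fold_id))
        model, fold_log = train_on_arrays(
            images[split.train_indices], labels[split.train_indices], fold_cfg
        )
        result = evaluate_model(model, images[split.test_indices], labels[split.test_indices])
        result.fold_id = split.fold_id
        out.folds.append(result)
        out.epoch_loss.append(fold_log.epoch_loss[-1])
        out.epoch_accuracy.append(fold_log.epoch_accuracy[-1])
    return out
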