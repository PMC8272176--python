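"""Training protocol: BCE loss, Adam, plateau scheduler, CV, prediction.

Defaults follow the published recipe: Adam at an initial learning rate of
1e-4, dropping once to 1e-5 when validation loss stagnates, binary
cross-entropy loss, batch size 4, 100 epochs, 384x384 inputs, 5-fold
cross-validation, and the five basic geometric augmentations (horizontal
stretch, vertical stretch, shear, zoom, horizontal flip) applied to training
slices only. Everything is seeded; on a single CPU thread two runs with the
same seed are bit-identical.
"""

from __future__ import annotations

import copy
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import data_io, metrics, nn
from .architecture import ArchitectureConfig, CaseNet, build_model
from .data_io import AugmentationSpec, SliceSample

__all__ = [
    "TrainConfig",
    "TrainingRecord",
    "Adam",
    "bce_loss",
    "train",
    "cross_validate",
    "predict",
]


@dataclass
class TrainConfig:
    loss: str = "bce"
    optimizer: str = "adam"
    initial_lr: float = 1e-4
    plateau_lr: float = 1e-5
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    input_size: tuple[int, int] = (384, 384)
    folds: int = 5
    seed: int = 0
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    device: str = "cpu"

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        if self.plateau_lr >= self.initial_lr:
            raise ValueError("plateau_lr must be below initial_lr")
        if self.loss != "bce":
            raise ValueError("binary cross-entropy is the only supported loss")
        if self.optimizer != "adam":
            raise ValueError("Adam is the only supported optimizer")


@dataclass
class TrainingRecord:
    """Per-epoch bookkeeping of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    fold_index: int | None = None
    best_epoch: int | None = None
    n_augmented: int = 0

    def to_jsonl(self) -> str:
        import json

        lines = []
        for e in range(len(self.train_loss)):
            lines.append(
                json.dumps(
                    {
                        "epoch": e,
                        "train_loss": self.train_loss[e],
                        "val_loss": self.val_loss[e],
                        "val_dsc": self.val_dsc[e],
                        "lr": self.lr_trace[e],
                    }
                )
            )
        return "\n".join(lines) + "\n"


class Adam:
    """Adam with the conventional moment defaults (b1=0.9, b2=0.999)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            p.data = p.data - (self.lr * update).astype(p.data.dtype)


def bce_loss(pred_probs, mask, eps: float = 1e-7) -> float:
    """Mean pixelwise binary cross-entropy with probability clipping."""
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(mask, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs mask {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())


def _stack_batch(samples):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    msks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return imgs, msks


def _evaluate(model, samples, batch_size):
    """Validation loss and mean per-slice DSC on untransformed slices."""
    losses, dscs = [], []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        imgs, msks = _stack_batch(chunk)
        probs = model.forward(imgs).data
        losses.append(bce_loss(probs, msks) * len(chunk))
        for j, s in enumerate(chunk):
            c = metrics.confusion((probs[j, 0] >= 0.5).astype(np.uint8), s.mask)
            dscs.append(metrics.dsc(c))
    return sum(losses) / len(samples), float(np.mean(dscs))


def train(
    model: CaseNet,
    train_samples: list[SliceSample],
    val_samples: list[SliceSample],
    cfg: TrainConfig,
    checkpoint_path=None,
    restore_best: bool = True,
) -> tuple[CaseNet, TrainingRecord]:
    """Run the full training protocol on one train/validation split.

    Training slices are augmented on the fly; validation slices never are.
    The learning rate drops once to ``plateau_lr`` after ``plateau_patience``
    epochs without a validation-loss improvement of ``plateau_min_delta``.
    The best-validation-loss weights are checkpointed and (by default)
    restored into the returned model.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    record = TrainingRecord()
    best_loss, best_state, since_improve = np.inf, None, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [
                data_io.augment(train_samples[i], cfg.augmentation, rng) for i in idx
            ]
            record.n_augmented += len(batch)
            imgs, msks = _stack_batch(batch)
            opt.zero_grad()
            out = model.forward(imgs)
            loss = nn.bce(out, msks)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(batch))
        val_loss, val_dsc = _evaluate(model, val_samples, cfg.batch_size)
        record.train_loss.append(sum(epoch_losses) / len(train_samples))
        record.val_loss.append(val_loss)
        record.val_dsc.append(val_dsc)
        record.lr_trace.append(opt.lr)

        if val_loss < best_loss - cfg.plateau_min_delta:
            best_loss, since_improve = val_loss, 0
            record.best_epoch = epoch
            best_state = [p.copy() for p in model.state_arrays()]
            if checkpoint_path is not None:
                from .architecture import save_checkpoint

                save_checkpoint(model, checkpoint_path)
        else:
            since_improve += 1
            if since_improve >= cfg.plateau_patience and opt.lr > cfg.plateau_lr:
                opt.lr = cfg.plateau_lr  # single reduction, as published
                since_improve = 0

    if restore_best and best_state is not None:
        model.load_state_arrays(best_state)
    return model, record


def cross_validate(
    arch_cfg: ArchitectureConfig,
    samples: list[SliceSample],
    cfg: TrainConfig,
) -> tuple[list[TrainingRecord], dict]:
    """k-fold patient-level cross-validation.

    Each fold trains a freshly initialised model on the fit patients and
    validates on the held-out patients. Returns per-fold records and an
    aggregate of the best-epoch validation DSC as mean +/- std.
    """
    by_patient = defaultdict(list)
    for s in samples:
        by_patient[s.patient_id].append(s)
    folds = data_io.make_folds(sorted(by_patient), k=cfg.folds, seed=cfg.seed)
    records, fold_dscs = [], []
    for fold_idx, (fit_ids, hold_ids) in enumerate(folds):
        fit = [s for pid in fit_ids for s in by_patient[pid]]
        hold = [s for pid in hold_ids for s in by_patient[pid]]
        model = build_model(arch_cfg, seed=cfg.seed + fold_idx)
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.seed = cfg.seed + fold_idx
        _, rec = train(model, fit, hold, fold_cfg)
        rec.fold_index = fold_idx
        records.append(rec)
        best = rec.best_epoch if rec.best_epoch is not None else len(rec.val_dsc) - 1
        fold_dscs.append(rec.val_dsc[best])
    fold_dscs = np.asarray(fold_dscs)
    aggregate = {
        "val_dsc_mean": float(fold_dscs.mean()),
        "val_dsc_std": float(fold_dscs.std(ddof=1)) if len(fold_dscs) > 1 else 0.0,
        "per_fold_val_dsc": [float(v) for v in fold_dscs],
    }
    return records, aggregate


def predict(model: CaseNet, image: np.ndarray, threshold: float = 0.5):
    """Segment one normalized slice: returns ``(binary_mask, probability_map)``."""
    image = np.asarray(image, dtype=np.float32)
    if image.shape != model.cfg.input_size:
        raise ValueError(
            f"image shape {image.shape} != model input {model.cfg.input_size}; "
            "resize or regenerate at the configured size"
        )
    probs = model.forward(image).data[0, 0]
    return (probs >= threshold).astype(np.uint8), probs
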