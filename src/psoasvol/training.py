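"""Dice-loss training, learning-rate sweep and k-fold cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .augment import AugmentationSpec, TrainingSample, build_training_set
from .core import MuscleCrop
from .metrics import confusion_counts, dsc
from .network import Adam, NetworkSpec, SegmentationNet, build_network
from .preprocess import SubjectCrops
from .quantify import mask_to_volume_ml

#: soft-Dice smoothing, one voxel-equivalent (avoids 0/0 on empty masks)
DICE_EPS = 1.0

DEFAULT_SWEEP_GRID = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 3
    epochs: int = 100
    seed: int = 0
    sweep_grid: Tuple[float, ...] = DEFAULT_SWEEP_GRID
    #: augmentation applied to the training subjects; None = use the two
    #: prepared crops per subject as-is
    augmentation: Optional[AugmentationSpec] = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: List[str]
    test_ids: List[str]


def soft_dice_loss(probabilities: np.ndarray, mask: np.ndarray,
                   eps: float = DICE_EPS) -> float:
    """``1 - (2 sum(p*m) + eps) / (sum(p) + sum(m) + eps)``."""
    p = np.asarray(probabilities, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {m.shape}")
    inter = float((p * m).sum())
    denom = float(p.sum() + m.sum()) + eps
    return 1.0 - (2.0 * inter + eps) / denom


def soft_dice_loss_grad(probabilities: np.ndarray, mask: np.ndarray,
                        eps: float = DICE_EPS):
    """Loss and its gradient with respect to the probabilities."""
    p = np.asarray(probabilities, dtype=np.float32)
    m = np.asarray(mask, dtype=np.float32)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {m.shape}")
    inter = float((p * m).sum())
    denom = float(p.sum() + m.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    grad = (num / denom ** 2 - 2.0 * m / denom).astype(np.float32)
    return loss, grad


def make_folds(subject_ids: Sequence[str], k: int, seed: int = 0) -> List[FoldSplit]:
    """Seeded shuffle then partition into k test sets of near-equal size."""
    ids = list(subject_ids)
    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} invalid for {len(ids)} subjects")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    chunks = np.array_split(np.arange(len(ids)), k)
    folds = []
    for f, chunk in enumerate(chunks):
        test = [shuffled[i] for i in chunk]
        test_set = set(test)
        train = [s for s in shuffled if s not in test_set]
        folds.append(FoldSplit(fold_id=f, train_ids=train, test_ids=test))
    return folds


def _sample_arrays(samples) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for s in samples:
        crop = s.crop if isinstance(s, TrainingSample) else s
        if isinstance(crop, MuscleCrop):
            if crop.mask is None:
                raise ValueError("training crops must carry masks")
            out.append((crop.intensities, crop.mask))
        else:
            x, m = crop
            out.append((np.asarray(x, np.float32), np.asarray(m)))
    return out


@dataclass
class TrainResult:
    net: SegmentationNet
    loss_history: List[float]
    best_epoch: int
    best_loss: float


def train_model(
    samples,
    config: TrainConfig,
    network_spec: NetworkSpec = NetworkSpec(),
    net: Optional[SegmentationNet] = None,
) -> TrainResult:
    """Adam / soft-Dice training with best-loss checkpointing.

    The fixed epoch budget stands in for "until convergence"; the
    returned network carries the weights of the best-mean-loss epoch.
    Fully deterministic given ``config.seed``.
    """
    pairs = _sample_arrays(samples)
    if not pairs:
        raise ValueError("no training samples")
    if net is None:
        net = build_network(network_spec, seed=config.seed)
    net.check_input_shape(pairs[0][0].shape)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1CE]))
    history: List[float] = []
    best_loss, best_epoch, best_weights = np.inf, -1, None
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = np.stack([pairs[i][0] for i in idx])[:, None]
            m = np.stack([pairs[i][1] for i in idx])[:, None].astype(np.float32)
            probs = net.forward(x)
            grads = np.empty_like(probs)
            for j in range(len(idx)):
                loss_j, g = soft_dice_loss_grad(probs[j, 0], m[j, 0])
                grads[j, 0] = g
                losses.append(loss_j)
            opt.zero_grad()
            net.backward(grads / len(idx))
            opt.step()
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        if mean_loss < best_loss:
            best_loss, best_epoch = mean_loss, epoch
            best_weights = net.get_weights()
    if best_weights is not None:
        net.set_weights(best_weights)
    return TrainResult(net=net, loss_history=history,
                       best_epoch=best_epoch, best_loss=best_loss)


def learning_rate_sweep(
    samples,
    grid: Sequence[float] = DEFAULT_SWEEP_GRID,
    config: TrainConfig = TrainConfig(),
    network_spec: NetworkSpec = NetworkSpec(),
    sweep_epochs: int = 10,
) -> pd.DataFrame:
    """Short fixed-epoch run per rate; ``selected`` marks the argmin."""
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for lr in grid:
        cfg = replace(config, learning_rate=lr, epochs=sweep_epochs)
        result = train_model(samples, cfg, network_spec)
        rows.append({"learning_rate": lr, "final_loss": result.loss_history[-1]})
    df = pd.DataFrame(rows)
    df["selected"] = df["final_loss"] == df["final_loss"].min()
    return df


@dataclass
class FoldResult:
    fold_id: int
    test_ids: List[str]
    dsc_mean: float
    dsc_sd: float


@dataclass
class CVReport:
    """Per-fold out-of-sample Dice summaries plus per-subject volume
    pairs for agreement analysis."""

    folds: List[FoldResult]
    per_subject: pd.DataFrame  # subject_id, fold, dsc, auto_ml, manual_ml
    pooled_dsc_mean: float
    pooled_dsc_sd: float

    def volume_pairs(self):
        return list(zip(self.per_subject["auto_ml"], self.per_subject["manual_ml"]))


def _evaluate_subject(net, subj: SubjectCrops, threshold: float):
    scores, auto_ml, manual_ml = [], 0.0, 0.0
    for crop in (subj.left, subj.right):
        probs = net.forward(crop.intensities[None, None])[0, 0]
        pred = (probs >= threshold).astype(np.uint8)
        scores.append(dsc(confusion_counts(pred, crop.mask)))
        auto_ml += mask_to_volume_ml(pred, crop.voxel_mm)
        manual_ml += mask_to_volume_ml(crop.mask, crop.voxel_mm)
    # per-muscle scores averaged per subject
    return float(np.mean(scores)), auto_ml, manual_ml


def cross_validate(
    subjects: Sequence[SubjectCrops],
    k: int,
    train_config: TrainConfig,
    network_spec: NetworkSpec = NetworkSpec(),
    threshold: float = 0.5,
) -> CVReport:
    """Train k models, each evaluated only on its held-out subjects."""
    by_id = {s.subject_id: s for s in subjects}
    for s in subjects:
        if s.left.mask is None or s.right.mask is None:
            raise ValueError(f"subject {s.subject_id} is not annotated")
    folds = make_folds(list(by_id), k, seed=train_config.seed)
    fold_results, rows = [], []
    for fold in folds:
        train_subjects = [by_id[i] for i in fold.train_ids]
        if train_config.augmentation is not None:
            samples = build_training_set(train_subjects, train_config.augmentation)
        else:
            samples = [c for s in train_subjects for c in (s.left, s.right)]
        cfg = replace(train_config,
                      seed=int(np.random.SeedSequence(
                          [train_config.seed, fold.fold_id]).generate_state(1)[0]))
        result = train_model(samples, cfg, network_spec)
        scores = []
        for sid in fold.test_ids:
            score, auto_ml, manual_ml = _evaluate_subject(
                result.net, by_id[sid], threshold)
            scores.append(score)
            rows.append({"subject_id": sid, "fold": fold.fold_id, "dsc": score,
                         "auto_ml": auto_ml, "manual_ml": manual_ml})
        fold_results.append(FoldResult(
            fold_id=fold.fold_id, test_ids=fold.test_ids,
            dsc_mean=float(np.mean(scores)),
            dsc_sd=float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
        ))
    per_subject = pd.DataFrame(rows)
    return CVReport(
        folds=fold_results,
        per_subject=per_subject,
        pooled_dsc_mean=float(per_subject["dsc"].mean()),
        pooled_dsc_sd=float(per_subject["dsc"].std(ddof=1)),
    )
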