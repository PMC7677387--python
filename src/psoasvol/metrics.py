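"""Segmentation overlap (Dice) and Bland-Altman agreement analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class BlandAltmanSummary:
    """Bias and 95% limits of agreement of paired percent differences."""

    bias: float
    loa_lower: float
    loa_upper: float
    n: int
    pct_diff: np.ndarray


def confusion_counts(prediction: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    prediction = np.asarray(prediction)
    truth = np.asarray(truth)
    if prediction.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {prediction.shape} vs {truth.shape}"
        )
    p = prediction.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def dsc(counts: ConfusionCounts) -> float:
    """Dice score 2TP / (FP + 2TP + FN); undefined when all counts are 0."""
    denom = counts.fp + 2 * counts.tp + counts.fn
    if denom == 0:
        raise ValueError("DSC undefined: prediction and truth are both empty")
    return 2.0 * counts.tp / denom


def dice_score(prediction: np.ndarray, truth: np.ndarray) -> float:
    return dsc(confusion_counts(prediction, truth))


def bland_altman(pairs: Sequence[Tuple[float, float]]) -> BlandAltmanSummary:
    """Agreement between automated and manual volumes.

    Percent difference per pair is 100 * (auto - manual) / pairwise
    mean; limits of agreement are bias +/- 1.96 * sample SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (auto, manual) tuples")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("Bland-Altman requires at least two pairs")
    auto, manual = arr[:, 0], arr[:, 1]
    if (auto <= 0).any() or (manual <= 0).any():
        raise ValueError("volumes must be positive")
    pct = 100.0 * (auto - manual) / ((auto + manual) / 2.0)
    bias = float(pct.mean())
    sd = float(pct.std(ddof=1))
    return BlandAltmanSummary(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=n,
        pct_diff=pct,
    )


def bland_altman_plot(summary: BlandAltmanSummary, means: np.ndarray, path) -> None:
    """Write the classic agreement plot to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, summary.pct_diff, s=8, alpha=0.6)
    for y, style in ((summary.bias, "--"), (summary.loa_lower, ":"),
                     (summary.loa_upper, ":")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of methods (ml)")
    ax.set_ylabel("Difference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
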