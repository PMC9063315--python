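"""Joint segmentation loss, pixel metrics, and paired significance testing.

The training objective is the sum of a soft Dice loss and binary
cross-entropy: Dice drives image-level overlap (robust to the optic disc
occupying only a few percent of pixels), BCE supervises every pixel.
Evaluation uses the Dice similarity coefficient Dsc = 2TP/(2TP+FP+FN) and
sensitivity Sen = TP/(TP+FN) computed from pixel confusion counts, and
model comparisons use a two-sided paired t-test on per-image Dsc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "dice_loss",
    "bce_loss",
    "total_loss",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dsc",
    "sen",
    "paired_t_test",
    "write_metrics_csv",
    "write_significance_csv",
]

logger = logging.getLogger(__name__)

DICE_SMOOTH = 1.0
PROB_CLIP = 1e-7


def _check_shapes(x, y):
    if x.shape != y.shape:
        raise ValueError(f"prediction and target shapes differ: {x.shape} vs {y.shape}")


def dice_loss(x, y, smooth: float = DICE_SMOOTH) -> Tensor:
    """Soft Dice loss 1 - 2(sum xy + eps)/(sum x + sum y + eps).

    ``x`` holds probabilities in [0,1], ``y`` a binary mask; the smoothing
    term keeps the loss (and its gradient) finite on empty masks.
    """
    x, y = as_tensor(x), as_tensor(y)
    _check_shapes(x, y)
    inter = (x * y).sum()
    return 1.0 - (2.0 * inter + smooth) / (x.sum() + y.sum() + smooth)


def bce_loss(x, y, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy, averaged per pixel (``reduction='sum'`` for the
    raw pixel sum). Probabilities are clipped away from {0,1} before logs."""
    x, y = as_tensor(x), as_tensor(y)
    _check_shapes(x, y)
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    xc = x.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    ll = y * xc.log() + (1.0 - y) * (1.0 - xc).log()
    return -(ll.mean() if reduction == "mean" else ll.sum())


def total_loss(x, y, smooth: float = DICE_SMOOTH, bce_reduction: str = "mean") -> Tensor:
    """Joint objective: exact sum of the Dice and BCE components."""
    return dice_loss(x, y, smooth) + bce_loss(x, y, bce_reduction)


# ---------------------------------------------------------------------------
# confusion accounting and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(a) -> np.ndarray:
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"expected a 0/1 mask; found values {vals[:5]}")
    return a.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Pixel confusion counts between two same-shape binary masks."""
    p, t = _as_binary(pred), _as_binary(truth)
    _check_shapes(p, t)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    Both masks empty means a vacuously perfect match: 1.0 by convention
    (logged), so an image with no target cannot dominate an average.
    """
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        logger.info("dsc: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * counts.tp / denom


def sen(counts: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN); undefined when the ground truth is empty."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise ValueError("sensitivity undefined for an empty ground-truth mask")
    return counts.tp / denom


def paired_t_test(scores_a, scores_b):
    """Two-sided paired t-test on per-image score differences.

    Returns ``(t, p)``. Identical score lists (all-zero differences) yield
    ``(0.0, 1.0)`` by convention, logged, rather than a NaN statistic.
    """
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test needs equally long score lists")
    if a.size < 3:
        raise ValueError("paired test needs at least 3 paired scores")
    if np.allclose(a - b, 0.0, atol=0.0):
        logger.info("paired_t_test: all differences zero; returning p = 1.0")
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# reporting


@dataclass
class MetricsReport:
    """Per-image Dsc/Sen with confusion counts, plus their arithmetic means.

    Images whose ground truth is empty are excluded from the Sen mean
    (sensitivity is undefined there); their count is recorded.
    """

    per_image: list  # of (image_id, dsc, sen_or_None, ConfusionCounts)

    @property
    def mean_dsc(self) -> float:
        return float(np.mean([r[1] for r in self.per_image]))

    @property
    def mean_sen(self) -> float:
        vals = [r[2] for r in self.per_image if r[2] is not None]
        return float(np.mean(vals))

    @property
    def n_sen_excluded(self) -> int:
        return sum(1 for r in self.per_image if r[2] is None)

    @classmethod
    def from_masks(cls, items) -> "MetricsReport":
        """items: iterable of (image_id, pred_mask, truth_mask)."""
        rows = []
        for image_id, pred, truth in items:
            c = confusion(pred, truth)
            s = sen(c) if (c.tp + c.fn) > 0 else None
            if s is None:
                logger.info("image %s has empty ground truth; excluded from Sen mean", image_id)
            rows.append((image_id, dsc(c), s, c))
        return cls(rows)


def write_metrics_csv(report: MetricsReport, path) -> None:
    """CSV of per-image rows plus a trailing mean summary row."""
    path = Path(path)
    lines = ["image_id,dsc,sen,tp,fp,fn,tn"]
    for image_id, d, s, c in report.per_image:
        sen_txt = "" if s is None else f"{s:.6f}"
        lines.append(f"{image_id},{d:.6f},{sen_txt},{c.tp},{c.fp},{c.fn},{c.tn}")
    lines.append(f"mean,{report.mean_dsc:.6f},{report.mean_sen:.6f},,,,")
    path.write_text("\n".join(lines) + "\n")


def write_significance_csv(comparisons, path) -> None:
    """comparisons: iterable of (label, t, p) -> small CSV table."""
    path = Path(path)
    lines = ["comparison,t,p"]
    for label, t, p in comparisons:
        lines.append(f"{label},{t:.6f},{p:.6g}")
    path.write_text("\n".join(lines) + "\n")
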