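"""Pixel-level segmentation scores and the Friedman method comparison.

All overlap scores are computed on the [0, 1] scale from the pixelwise
confusion counts; report helpers format them as percentages to two
decimals. The Hausdorff distance is taken between boundary pixel centres
in Euclidean pixel units (no mm conversion unless spacing is supplied by
the caller).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import chi2, rankdata, studentized_range

from .errors import DegenerateInputError, InputError
from .imgdata import BinaryMask

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "confusion_counts",
    "overlap_metrics",
    "hausdorff_distance",
    "evaluate_masks",
    "metrics_report",
    "friedman_test",
    "FriedmanResult",
]

DIFFERENT_MARK = "O"   # methods differ at alpha (Nemenyi)
EQUAL_MARK = "D"       # statistically indistinguishable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegMetrics:
    """The six pixel-level scores for one (prediction, truth) pair.

    acc/sen/jaccard/dice lie in [0,1], mcc in [-1,1], hausdorff in pixels.
    ``sen`` is NaN when the ground truth is empty (undefined, not zero).
    """

    acc: float
    sen: float
    mcc: float
    jaccard: float
    dice: float
    hausdorff: float

    def as_percent_row(self) -> dict[str, float]:
        """Table-ready row in the conventional column order, percentages."""
        return {
            "Mcc": round(self.mcc * 100, 2),
            "Acc": round(self.acc * 100, 2),
            "Sen": round(self.sen * 100, 2) if math.isfinite(self.sen) else float("nan"),
            "Jaccard": round(self.jaccard * 100, 2),
            "HD": round(self.hausdorff, 2),
            "DICE": round(self.dice * 100, 2),
        }


def confusion_counts(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN between a predicted and a reference mask."""
    if pred.shape != gt.shape:
        raise InputError(f"shape mismatch {pred.shape} vs {gt.shape}")
    p = pred.as_bool()
    g = gt.as_bool()
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def overlap_metrics(c: ConfusionCounts) -> SegMetrics:
    """Accuracy, sensitivity, MCC, Jaccard and Dice from confusion counts.

    Conventions: MCC is 0 when any denominator factor is 0; sensitivity is
    NaN when the truth is empty; a both-empty pair scores Dice = Jaccard =
    1 (perfect vacuous agreement, with a warning). Hausdorff is NaN here —
    use :func:`hausdorff_distance` or :func:`evaluate_masks`.
    """
    if c.total <= 0:
        raise InputError("empty confusion table")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = (tp + tn) / c.total
    sen = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if tp + fp + fn == 0:
        warnings.warn("both masks empty: vacuous perfect overlap", stacklevel=2)
        jaccard = dice = 1.0
    else:
        jaccard = tp / (tp + fp + fn)
        dice = 2 * tp / (2 * tp + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return SegMetrics(acc=acc, sen=sen, mcc=mcc, jaccard=jaccard,
                      dice=dice, hausdorff=float("nan"))


def _boundary_points(mask: BinaryMask) -> np.ndarray:
    m = mask.as_bool()
    eroded = ndi.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(m & ~eroded).astype(np.float64)


def hausdorff_distance(pred: BinaryMask, gt: BinaryMask) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels."""
    if pred.shape != gt.shape:
        raise InputError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if pred.area == 0 or gt.area == 0:
        raise DegenerateInputError("Hausdorff undefined for an empty mask")
    a = _boundary_points(pred)
    b = _boundary_points(gt)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def evaluate_masks(pred: BinaryMask, gt: BinaryMask) -> SegMetrics:
    """All six scores for one pair; Hausdorff is NaN if either mask is empty."""
    m = overlap_metrics(confusion_counts(pred, gt))
    hd = float("nan")
    if pred.area > 0 and gt.area > 0:
        hd = hausdorff_distance(pred, gt)
    return SegMetrics(acc=m.acc, sen=m.sen, mcc=m.mcc, jaccard=m.jaccard,
                      dice=m.dice, hausdorff=hd)


def metrics_report(pairs: list[SegMetrics]) -> pd.DataFrame:
    """Per-case table plus mean +/- sd summary rows (percent scale)."""
    rows = [m.as_percent_row() for m in pairs]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([df.mean(), df.std(ddof=1)], index=["mean", "sd"])
    return pd.concat([df, summary])


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: pd.Series
    critical_difference: float
    flags: pd.DataFrame  # pairwise marks: O = different, D = equal


def friedman_test(scores: pd.DataFrame, alpha: float = 0.05) -> FriedmanResult:
    """Friedman rank test across methods (columns) and cases (rows).

    Within-case ranks use mid-ranks for ties; the chi-square statistic
    carries the standard tie correction (and is defined as 0 when every
    case is a full tie). Pairwise difference flags use the Nemenyi
    critical difference at ``alpha``.
    """
    data = np.asarray(scores, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise InputError("need >= 2 methods and >= 2 cases")
    if np.isnan(data).any():
        raise InputError("scores contain NaN")
    n, k = data.shape  # n cases, k methods

    ranks = np.apply_along_axis(rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    mean_rank = (k + 1) / 2.0
    ss_between = n * np.sum((rank_sums / n - mean_rank) ** 2)
    ss_total = np.sum((ranks - mean_rank) ** 2)
    if ss_total == 0.0:  # every case fully tied
        stat = 0.0
    else:
        stat = (n * (k - 1)) * ss_between / ss_total
    p = float(chi2.sf(stat, k - 1))

    q = studentized_range.ppf(1 - alpha, k, np.inf) / math.sqrt(2.0)
    cd = float(q * math.sqrt(k * (k + 1) / (6.0 * n)))
    mean_ranks = rank_sums / n

    cols = list(scores.columns) if isinstance(scores, pd.DataFrame) else list(range(k))
    flags = pd.DataFrame(EQUAL_MARK, index=cols, columns=cols)
    for i in range(k):
        for j in range(k):
            if i != j and abs(mean_ranks[i] - mean_ranks[j]) >= cd:
                flags.iloc[i, j] = DIFFERENT_MARK
    return FriedmanResult(
        statistic=float(stat),
        p_value=p,
        mean_ranks=pd.Series(mean_ranks, index=cols),
        critical_difference=cd,
        flags=flags,
    )
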