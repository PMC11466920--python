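"""Segmentation evaluation metrics: IoU, Dice, pixel accuracy, HD95.

Overlap metrics come from the per-image confusion counts:

    IoU  = TP / (TP + FP + FN)
    Dice = 2*TP / ((TP + FP) + (TP + FN))
    ACC  = (TP + TN) / (TP + TN + FP + FN)

(Dice and IoU obey Dice = 2*IoU / (1 + IoU).)  When both masks are empty the
overlap metrics are reported as 1.0 by convention (perfect agreement on the
absence of any lesion) and a note is logged.

HD95 is the 95th percentile of boundary-to-boundary Euclidean distances.  By
default the boundary is the mask minus its one-pixel erosion, and the two
directed nearest-neighbour distance sets (prediction→truth and
truth→prediction) are pooled before taking the percentile — the de-facto
convention of medical-segmentation tooling; a max-of-directed-percentiles
variant and an all-pixel variant are available behind flags.  If either mask
is empty the distance is undefined: NaN is returned and dataset aggregation
excludes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ShapeError

__all__ = [
    "ConfusionCounts",
    "confusion",
    "iou",
    "dice",
    "acc",
    "hd95",
    "evaluate_masks",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_bool(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    p = _as_bool(pred)
    g = _as_bool(gt)
    if p.shape != g.shape:
        raise ShapeError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        logger.info("both masks empty; IoU reported as 1.0 by convention")
        return 1.0
    return c.tp / denom


def dice(c: ConfusionCounts) -> float:
    denom = (c.tp + c.fp) + (c.tp + c.fn)
    if denom == 0:
        logger.info("both masks empty; Dice reported as 1.0 by convention")
        return 1.0
    return 2.0 * c.tp / denom


def acc(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def hd95(
    pred,
    gt,
    spacing: float = 1.0,
    percentile: float = 95.0,
    boundary: bool = True,
    directed: str = "pooled",
) -> float:
    """95th-percentile Hausdorff distance between two binary masks.

    Returns NaN (with a log note) if either mask is empty.  ``percentile=100``
    gives the classical Hausdorff distance.
    """
    p = _as_bool(pred)
    g = _as_bool(gt)
    if p.shape != g.shape:
        raise ShapeError(f"mask shapes differ: {p.shape} vs {g.shape}")
    if not p.any() or not g.any():
        logger.info("empty mask in HD95; returning NaN (excluded from aggregates)")
        return float("nan")
    if boundary:
        p_pts = np.argwhere(_boundary(p))
        g_pts = np.argwhere(_boundary(g))
    else:
        p_pts = np.argwhere(p)
        g_pts = np.argwhere(g)
    d_pg = cKDTree(g_pts).query(p_pts)[0]
    d_gp = cKDTree(p_pts).query(g_pts)[0]
    if directed == "pooled":
        value = np.percentile(np.concatenate([d_pg, d_gp]), percentile)
    elif directed == "max":
        value = max(np.percentile(d_pg, percentile), np.percentile(d_gp, percentile))
    else:
        raise ValueError(f"unknown directed mode {directed!r}")
    return float(value) * spacing


def evaluate_masks(pairs, spacing: float = 1.0) -> pd.DataFrame:
    """Per-image IoU/Dice/ACC/HD95 for (pred, gt) mask pairs.

    Aggregation is the mean of per-image metrics; NaN HD95 values (empty
    masks) are excluded from the HD95 mean.
    """
    rows = []
    for i, (pred, gt) in enumerate(pairs):
        c = confusion(pred, gt)
        rows.append(
            {
                "image": i,
                "iou": iou(c),
                "dice": dice(c),
                "acc": acc(c),
                "hd95": hd95(pred, gt, spacing=spacing),
            }
        )
    return pd.DataFrame(rows)
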