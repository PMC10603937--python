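"""Dice-score evaluation, per-class report tables, and cross-validation
aggregation.

Conventions: scores are computed on hard (argmax) masks; classes absent
from both ground truth and prediction in an image are excluded from that
image's mean (with one class each in neither mask there is nothing to
score); background can be excluded from reported tables, mirroring how
layer-wise results are usually tabulated.  Aggregation across images is
the mean of per-image scores, not a pooled-pixel score; fold aggregation
reports mean ± sample standard deviation (ddof = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import LabelScheme


def _binary_dice_hard(gt: np.ndarray, pred: np.ndarray) -> float:
    inter = np.logical_and(gt, pred).sum()
    denom = gt.sum() + pred.sum()
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def dice_score_image(gt_mask: np.ndarray, pred_mask: np.ndarray,
                     scheme: LabelScheme | int,
                     include_background: bool = True,
                     skip_absent: bool = True) -> tuple[dict[int, float], float]:
    """Per-class and overall Dice for one image pair (hard masks).

    Returns ``(per_class, overall)`` where ``per_class`` maps class index to
    score (``nan`` for classes skipped as absent from both masks) and
    ``overall`` is the unweighted mean over the scored classes.  Symmetric
    in its two arguments.
    """
    gt_mask = np.asarray(gt_mask)
    pred_mask = np.asarray(pred_mask)
    if gt_mask.shape != pred_mask.shape:
        raise ValueError(f"shape mismatch: {gt_mask.shape} vs {pred_mask.shape}")
    C = scheme if isinstance(scheme, int) else scheme.C
    per_class: dict[int, float] = {}
    scores = []
    first = 0 if include_background else 1
    for c in range(first, C):
        g = gt_mask == c
        p = pred_mask == c
        if skip_absent and not g.any() and not p.any():
            per_class[c] = float("nan")
            continue
        s = _binary_dice_hard(g, p)
        per_class[c] = s
        scores.append(s)
    overall = float(np.mean(scores)) if scores else float("nan")
    return per_class, overall


@dataclass
class DiceReport:
    """Class-wise Dice table over a dataset, Table-6 style."""

    per_class: dict[int, float]
    overall: float
    per_image: dict[str, tuple[dict[int, float], float]]
    n_images: int
    class_names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Rows = classes + overall, columns = images + aggregate mean."""
        classes = sorted(self.per_class)
        names = {c: (self.class_names[c] if c < len(self.class_names) else str(c))
                 for c in classes}
        data = {}
        for img_id, (pc, ov) in self.per_image.items():
            data[img_id] = [pc.get(c, float("nan")) for c in classes] + [ov]
        data["aggregate"] = [self.per_class[c] for c in classes] + [self.overall]
        index = [names[c] for c in classes] + ["overall"]
        return pd.DataFrame(data, index=index)


def dice_report(pairs, scheme: LabelScheme | int,
                include_background: bool = True) -> DiceReport:
    """Aggregate Dice over ``(image_id, gt_mask, pred_mask)`` triples.

    Per-class entries are means over the images in which the class is
    scored; the overall value is the mean of the aggregated per-class
    entries.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty dataset")
    C = scheme if isinstance(scheme, int) else scheme.C
    names = () if isinstance(scheme, int) else scheme.names
    per_image: dict[str, tuple[dict[int, float], float]] = {}
    acc: dict[int, list[float]] = {}
    for img_id, gt, pred in pairs:
        pc, ov = dice_score_image(gt, pred, C,
                                  include_background=include_background)
        per_image[str(img_id)] = (pc, ov)
        for c, s in pc.items():
            if not np.isnan(s):
                acc.setdefault(c, []).append(s)
    per_class = {c: float(np.mean(v)) for c, v in sorted(acc.items())}
    overall = float(np.mean(list(per_class.values())))
    return DiceReport(per_class=per_class, overall=overall,
                      per_image=per_image, n_images=len(pairs),
                      class_names=tuple(names))


@dataclass
class CVSummary:
    """Cross-validation fold scores summarised as mean ± sample std."""

    fold_scores: list[float]
    mean: float
    std: float

    def format_percent(self) -> str:
        return f"{100 * self.mean:.2f}±{100 * self.std:.2f}"


def cv_aggregate(fold_scores) -> CVSummary:
    scores = [float(s) for s in fold_scores]
    if len(scores) < 2:
        raise ValueError("need at least two folds to aggregate")
    return CVSummary(fold_scores=scores,
                     mean=float(np.mean(scores)),
                     std=float(np.std(scores, ddof=1)))
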