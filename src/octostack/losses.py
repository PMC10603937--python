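"""Differentiable segmentation losses: Dice, Lovász-Softmax, Tversky, and
their fixed-weight combination.

All losses are defined on class-probability maps and are differentiable, so
the same code serves training (autograd tensors) and analysis (plain numpy
arrays; a float is returned when every input is plain).  Probability maps
are ``(C, H, W)`` or batched ``(N, C, H, W)``; batched inputs pool the batch
axis into the pixel population.

Soft set sizes are used throughout: for ground truth indicator ``g`` and
probability ``p``, ``|X ∩ Y| = Σ g·p``, ``|X − Y| = Σ g·(1−p)``,
``|Y − X| = Σ (1−g)·p``.  Hard (argmax) sets appear only in the metrics
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, as_tensor
from .schema import one_hot

DEFAULT_SMOOTH = 1e-6


@dataclass(frozen=True)
class TverskyParams:
    """Asymmetry weights of the Tversky index.

    ``alpha`` multiplies ``|X − Y|`` and ``beta`` multiplies ``|Y − X|``
    (with X the ground truth); ``alpha = beta = 0.5`` recovers the Dice
    loss exactly.  Note the common prose that pairs alpha with false
    positives refers to the reverse orientation of X and Y; this
    implementation follows the formula with X as ground truth, under which
    ``|X − Y|`` is the false-negative mass.
    """

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha + self.beta == 0:
            raise ValueError("alpha + beta must be positive")


@dataclass(frozen=True)
class CombinedLossConfig:
    """Weights of the compound loss 0.5·Dice + 0.3·Lovász + 0.2·Tversky."""

    w_dice: float = 0.5
    w_lovasz: float = 0.3
    w_tversky: float = 0.2
    tversky: TverskyParams = field(default_factory=TverskyParams)
    smooth: float = DEFAULT_SMOOTH
    lovasz_class_mode: str = "present"

    def __post_init__(self):
        if min(self.w_dice, self.w_lovasz, self.w_tversky) < 0:
            raise ValueError("loss weights must be non-negative")


def _maybe_float(out: Tensor, inputs) -> "Tensor | float":
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return float(out.data)


def _check_shapes(a, b):
    sa = a.shape if not isinstance(a, Tensor) else a.data.shape
    sb = b.shape if not isinstance(b, Tensor) else b.data.shape
    if sa != sb:
        raise ValueError(f"shape mismatch: {sa} vs {sb}")


def binary_dice(X, Y, smooth: float = DEFAULT_SMOOTH):
    """Sørensen–Dice score 2|X∩Y| / (|X|+|Y|), soft sets allowed.

    Empty-vs-empty with ``smooth == 0`` is defined as a perfect score of 1
    (the 0/0 convention; with positive smoothing this is automatic).
    """
    _check_shapes(X, Y)
    Xt, Yt = as_tensor(X), as_tensor(Y)
    denom = float(Xt.data.sum() + Yt.data.sum())
    if smooth == 0 and denom == 0:
        return _maybe_float(Tensor(1.0), (X, Y))
    score = ((Xt * Yt).sum() * 2.0 + smooth) / (Xt.sum() + Yt.sum() + smooth)
    return _maybe_float(score, (X, Y))


def _class_axes(arr_shape):
    """(class axis size, per-class reduction axes) for (C,H,W) or (N,C,H,W)."""
    if len(arr_shape) == 3:
        return arr_shape[0], 0
    if len(arr_shape) == 4:
        return arr_shape[1], 1
    raise ValueError(f"expected (C,H,W) or (N,C,H,W), got {arr_shape}")


def _per_class(arr, c: int, class_axis: int):
    if class_axis == 0:
        return arr[c]
    return arr[:, c]


def multiclass_dice_loss(gt_one_hot, P, smooth: float = DEFAULT_SMOOTH):
    """Mean over classes of (1 − binary Dice) between indicator and
    probability channels."""
    _check_shapes(gt_one_hot, P)
    gt_t, p_t = as_tensor(gt_one_hot), as_tensor(P)
    C, ax = _class_axes(gt_t.data.shape)
    total = None
    for c in range(C):
        score = binary_dice(_per_class(gt_t, c, ax), _per_class(p_t, c, ax),
                            smooth=smooth)
        term = 1.0 - as_tensor(score)
        total = term if total is None else total + term
    loss = total * (1.0 / C)
    return _maybe_float(loss, (gt_one_hot, P))


def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Jaccard-extension weights for a 0/1 vector sorted by decreasing error.

    ``J(i) = 1 − intersection_i / union_i`` over growing mispredicted
    prefixes; the weights are the first differences of J and are
    non-negative, summing to the Jaccard error of the fully mispredicted
    set.
    """
    gt_sorted = np.asarray(gt_sorted, dtype=np.float64)
    p = gt_sorted.sum()
    intersection = p - np.cumsum(gt_sorted)
    union = p + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if gt_sorted.size > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_softmax(gt_mask, P, class_mode: str = "present"):
    """Lovász-Softmax loss: the convex Lovász extension of the Jaccard loss.

    Per class, pixel errors ``|gt_c − p_c|`` are sorted in decreasing order
    (stable) and weighted by the Jaccard-extension differences computed from
    the sorted ground truth; the loss is the mean over classes present in
    the ground truth (``class_mode="present"``) or over all classes
    (``"all"``).  At any hard one-hot prediction the per-class value equals
    1 − IoU of that class.
    """
    if class_mode not in ("present", "all"):
        raise ValueError("class_mode must be 'present' or 'all'")
    p_t = as_tensor(P)
    C, ax = _class_axes(p_t.data.shape)
    mask = np.asarray(gt_mask if not isinstance(gt_mask, Tensor) else gt_mask.data)
    mask = mask.astype(np.int64)
    if ax == 1 and mask.ndim == 2:
        raise ValueError("batched P needs a batched (N,H,W) mask")
    present = np.unique(mask)
    classes = [c for c in range(C) if c in present] if class_mode == "present" \
        else list(range(C))
    if not classes:
        raise ValueError("ground truth contains no classes")
    total = None
    for c in classes:
        fg = (mask == c).astype(p_t.data.dtype).ravel()
        pc = _per_class(p_t, c, ax).flatten()
        errors = (as_tensor(fg) - pc).abs()
        perm = np.argsort(-errors.data, kind="stable")
        weights = lovasz_grad(fg[perm])
        term = (errors.take(perm) * weights).sum()
        total = term if total is None else total + term
    loss = total * (1.0 / len(classes))
    return _maybe_float(loss, (gt_mask, P))


def tversky_loss(gt_one_hot, P, params: TverskyParams | None = None,
                 smooth: float = DEFAULT_SMOOTH):
    """Tversky loss 1 − (|X∩Y|+s) / (|X∩Y| + α|X−Y| + β|Y−X| + s), mean
    over classes, with soft set sizes; generalizes Dice (α=β=0.5)."""
    params = params or TverskyParams()
    _check_shapes(gt_one_hot, P)
    gt_t, p_t = as_tensor(gt_one_hot), as_tensor(P)
    C, ax = _class_axes(gt_t.data.shape)
    total = None
    for c in range(C):
        g = _per_class(gt_t, c, ax)
        p = _per_class(p_t, c, ax)
        inter = (g * p).sum()
        fn = (g * (1.0 - p)).sum()          # |X − Y|
        fp = ((1.0 - g) * p).sum()          # |Y − X|
        denom_val = float(inter.data + params.alpha * fn.data
                          + params.beta * fp.data)
        if smooth == 0 and denom_val == 0:
            term = Tensor(0.0)              # empty-vs-empty: perfect
        else:
            index = (inter + smooth) / (inter + params.alpha * fn
                                        + params.beta * fp + smooth)
            term = 1.0 - index
        total = term if total is None else total + term
    loss = total * (1.0 / C)
    return _maybe_float(loss, (gt_one_hot, P))


def combined_loss(gt_mask, P, config: CombinedLossConfig | None = None,
                  n_classes: int | None = None):
    """Weighted compound loss  w_d·Dice + w_l·Lovász + w_t·Tversky
    (defaults 0.5 / 0.3 / 0.2).

    ``gt_mask`` is an integer label mask ((H,W) or (N,H,W)); the one-hot
    encoding for the Dice and Tversky terms is derived from it.
    """
    config = config or CombinedLossConfig()
    p_t = as_tensor(P)
    C, ax = _class_axes(p_t.data.shape)
    if n_classes is not None and n_classes != C:
        raise ValueError(f"P has {C} classes, expected {n_classes}")
    mask = np.asarray(gt_mask if not isinstance(gt_mask, Tensor) else gt_mask.data)
    mask = mask.astype(np.int64)
    if ax == 0:
        gt = one_hot(mask, C)
    else:
        gt = np.stack([one_hot(m, C) for m in mask])
    gt = gt.astype(p_t.data.dtype, copy=False)
    d = as_tensor(multiclass_dice_loss(gt, p_t, smooth=config.smooth))
    l = as_tensor(lovasz_softmax(mask, p_t, class_mode=config.lovasz_class_mode))
    t = as_tensor(tversky_loss(gt, p_t, params=config.tversky,
                               smooth=config.smooth))
    loss = config.w_dice * d + config.w_lovasz * l + config.w_tversky * t
    return _maybe_float(loss, (gt_mask, P))
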