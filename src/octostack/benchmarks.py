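"""Desk-scale benchmark protocols on synthetic phantoms.

These are the package's canonical CPU-sized study conditions: a
learnability smoke test (can a compact single-stack model segment moderate
-noise phantoms?), a refinement comparison on high-noise phantoms (does
adding the second, denoising stack at least match the single stack?), and
brute-force oracle deviations for the loss zoo.  Tests assert on these
quantities; the reproduction script reports them.

Problem sizes are deliberately small (64x64 or 32x32 phantoms, tens of
images, <=24 epochs) so every protocol runs in minutes on one CPU core.
"""

from __future__ import annotations

import itertools

import numpy as np

from .losses import (CombinedLossConfig, TverskyParams, combined_loss,
                     lovasz_grad, lovasz_softmax, multiclass_dice_loss,
                     tversky_loss)
from .network import default_spec
from .phantom import PhantomConfig, generate_dataset
from .schema import one_hot
from .training import TrainConfig, _evaluate, train

SMOKE_PHANTOMS = dict(width=64, height=64, n_layers=4)
HIGH_NOISE_PHANTOMS = dict(width=32, height=32, n_layers=4,
                           speckle_looks=1.0, gaussian_sigma=0.1)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,))
               .generate_state(1)[0] % (2 ** 31))


def smoke_learnability(seed: int = 0, n_train: int = 64, n_val: int = 16,
                       max_epochs: int = 20) -> list[float]:
    """Validation overall Dice of a single-stack TinyEncoder model on
    moderate-noise 5-class phantoms, one value per training seed.

    Conditions: 64x64 phantoms (4 tissue layers + background), default
    speckle/noise, batch 8, cosine schedule, three training seeds derived
    from ``seed``.
    """
    cfg = PhantomConfig(**SMOKE_PHANTOMS)
    train_s = generate_dataset(n_train, cfg, seed=_sub_seed(seed, 1))
    val_s = generate_dataset(n_val, cfg, seed=_sub_seed(seed, 2))
    dices = []
    for k in range(3):
        tc = TrainConfig(batch_size=8, max_epochs=max_epochs,
                         early_stop_patience=max_epochs,
                         seed=_sub_seed(seed, 10 + k))
        model, _ = train(default_spec(cfg.n_classes, n_stacks=1),
                         train_s, val_s, tc)
        _, dice = _evaluate(model, val_s, tc.loss, cfg.n_classes,
                            tc.batch_size)
        dices.append(float(dice))
    return dices


def stack_refinement_comparison(seed: int = 0, n_train: int = 64,
                                n_val: int = 24, max_epochs: int = 24) -> dict:
    """One-stack vs two-stack validation Dice on HIGH-noise phantoms
    (speckle_looks=1, additive sigma=0.1) under an identical budget.

    The second stack plays the denoiser role: it re-encodes the image
    together with stack 1's softmax output.  Returns per-seed scores and
    the two means; non-inferiority of the two-stack model is the claim
    under test.
    """
    cfg = PhantomConfig(**HIGH_NOISE_PHANTOMS)
    train_s = generate_dataset(n_train, cfg, seed=_sub_seed(seed, 3))
    val_s = generate_dataset(n_val, cfg, seed=_sub_seed(seed, 4))
    out: dict = {}
    for n_stacks in (1, 2):
        scores = []
        for k in range(3):
            tc = TrainConfig(batch_size=8, max_epochs=max_epochs,
                             early_stop_patience=max_epochs,
                             seed=_sub_seed(seed, 20 + k))
            model, _ = train(default_spec(cfg.n_classes, n_stacks=n_stacks),
                             train_s, val_s, tc)
            _, dice = _evaluate(model, val_s, tc.loss, cfg.n_classes,
                                tc.batch_size)
            scores.append(float(dice))
        out[n_stacks] = scores
    return {"single_stack": out[1], "two_stack": out[2],
            "single_mean": float(np.mean(out[1])),
            "two_mean": float(np.mean(out[2]))}


# -- loss-oracle deviations ----------------------------------------------------


def dice_loss_exhaustive_deviation() -> float:
    """Max |multiclass Dice loss - (1 - mean per-class set Dice)| over all
    4096 ordered pairs of 2x3 binary masks, smooth = 0.

    The oracle counts pixel sets directly (intersection and cardinalities),
    with empty-vs-empty scored 1.
    """
    worst = 0.0
    masks = [np.array(bits).reshape(2, 3)
             for bits in itertools.product((0, 1), repeat=6)]
    for a in masks:
        gt = one_hot(a, 2)
        for b in masks:
            loss = multiclass_dice_loss(gt, one_hot(b, 2), smooth=0)
            scores = []
            for c in range(2):
                x, y = (a == c), (b == c)
                denom = x.sum() + y.sum()
                scores.append(1.0 if denom == 0
                              else 2.0 * (x & y).sum() / denom)
            worst = max(worst, abs(loss - (1.0 - np.mean(scores))))
    return float(worst)


def lovasz_hard_iou_deviation(n_instances: int = 500, seed: int = 0) -> float:
    """Max deviation of the Lovász-Softmax loss from mean per-class
    (1 - IoU) at hard one-hot predictions."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        C = int(rng.integers(2, 6))
        h, w = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        gt = rng.integers(0, C, (h, w))
        pred = rng.integers(0, C, (h, w))
        vals = []
        for c in np.unique(gt):
            inter = ((gt == c) & (pred == c)).sum()
            union = ((gt == c) | (pred == c)).sum()
            vals.append(1 - inter / union if union else 0.0)
        got = lovasz_softmax(gt, one_hot(pred, C), "present")
        worst = max(worst, abs(got - float(np.mean(vals))))
    return float(worst)


def lovasz_choquet_deviation(n_instances: int = 40, seed: int = 0,
                             grid: int = 10_000) -> float:
    """Max deviation of the sorted-error Lovász loss from the level-set
    (Choquet) integral of the Jaccard set loss on <= 8-pixel instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 9))
        fg = rng.integers(0, 2, n).astype(float)
        if fg.sum() == 0:
            fg[int(rng.integers(n))] = 1.0
        p = rng.random(n)
        errors = np.abs(fg - p)
        perm = np.argsort(-errors, kind="stable")
        mine = float((errors[perm] * lovasz_grad(fg[perm])).sum())
        ts = np.linspace(0.0, 1.0, grid)
        total = fg.sum()
        vals = np.empty(grid)
        for i, t in enumerate(ts):
            S = errors >= t
            if not S.any():
                vals[i] = 0.0
            else:
                vals[i] = 1 - (total - fg[S].sum()) / (total + (1 - fg)[S].sum())
        worst = max(worst, abs(mine - float(np.trapezoid(vals, ts))))
    return float(worst)


def tversky_dice_identity_deviation(n_instances: int = 1000,
                                    seed: int = 0) -> float:
    """Max |Tversky(0.5, 0.5) - Dice loss| over random soft instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        C = int(rng.integers(2, 5))
        gt = one_hot(rng.integers(0, C, (4, 4)), C)
        P = np.moveaxis(rng.dirichlet(np.ones(C), size=(4, 4)), -1, 0)
        d = multiclass_dice_loss(gt, P, smooth=0)
        t = tversky_loss(gt, P, TverskyParams(0.5, 0.5), smooth=0)
        worst = max(worst, abs(d - t))
    return float(worst)


def combined_weighting_deviation(n_instances: int = 200, seed: int = 0) -> float:
    """Max deviation of the combined loss from the explicit weighted sum
    0.5*Dice + 0.3*Lovász + 0.2*Tversky of independently computed terms."""
    rng = np.random.default_rng(seed)
    cfg = CombinedLossConfig()
    worst = 0.0
    for _ in range(n_instances):
        C = int(rng.integers(2, 5))
        mask = rng.integers(0, C, (5, 5))
        P = np.moveaxis(rng.dirichlet(np.ones(C), size=(5, 5)), -1, 0)
        expected = (0.5 * multiclass_dice_loss(one_hot(mask, C), P,
                                               smooth=cfg.smooth)
                    + 0.3 * lovasz_softmax(mask, P)
                    + 0.2 * tversky_loss(one_hot(mask, C), P,
                                         smooth=cfg.smooth))
        worst = max(worst, abs(combined_loss(mask, P, cfg) - expected))
    return float(worst)
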