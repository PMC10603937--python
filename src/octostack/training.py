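"""Training protocol: augmentation, Adam + cosine-annealed learning rate,
early stopping, per-stack loss application, k-fold cross-validation, and
random-search hyperparameter tuning — all seeded and deterministic in
single-threaded runs.

Defaults follow the published protocol for peripapillary OCT segmentation:
Adam, initial learning rate 0.001 annealed cosine-wise to 1% of its initial
value, batch size 32, at most 75 epochs with early stopping, four-fold
cross-validation, factor-two dataset expansion by horizontal flips,
additive Gaussian noise, and contrast adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._layers import Adam
from ._tensor import Tensor, no_grad
from .losses import CombinedLossConfig, combined_loss
from .metrics import CVSummary, cv_aggregate, dice_score_image
from .network import StackedModel, StackedModelSpec, build_stacked
from .schema import ImageSample, kfold_split


@dataclass
class AugmentConfig:
    """Augmentation transforms: horizontal flip (image and mask together),
    additive Gaussian noise and multiplicative contrast (image only)."""

    hflip: bool = True
    gaussian_sigma: float = 0.02
    contrast_range: tuple[float, float] = (0.8, 1.2)
    expansion_factor: int = 2

    def __post_init__(self):
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.contrast_range[0] > self.contrast_range[1]:
            raise ValueError("contrast_range must be an interval")


@dataclass
class TrainConfig:
    """Optimizer, schedule, loss, and stack-coupling settings for one run."""

    lr_init: float = 0.001
    lr_final_factor: float = 0.01
    schedule: str = "cosine"              # or "cosine+warmup"
    warmup_epochs: int = 0
    batch_size: int = 32
    max_epochs: int = 75
    early_stop_patience: int = 10
    loss: CombinedLossConfig = field(default_factory=CombinedLossConfig)
    stack_mode: str = "joint"             # or "sequential"
    aux_weight: float = 0.4               # stack-1 loss weight in joint mode
    clip_norm: float | None = 5.0         # global gradient-norm clip
    seed: int = 0

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0 < self.lr_final_factor <= 1:
            raise ValueError("lr_final_factor must be in (0, 1]")
        if self.batch_size < 1 or self.early_stop_patience < 1:
            raise ValueError("batch_size and patience must be >= 1")
        if self.stack_mode not in ("joint", "sequential"):
            raise ValueError("stack_mode must be 'joint' or 'sequential'")


@dataclass
class SearchSpace:
    """Discrete grids for random search (drawn uniformly with replacement)."""

    grids: dict = field(default_factory=lambda: {
        "optimizer": ["adam"],
        "lr_init": [0.001],
        "batch_size": [16, 32, 64],
    })
    budget: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if any(len(v) == 0 for v in self.grids.values()):
            raise ValueError("every grid must be non-empty")


def augment_sample(sample: ImageSample, config: AugmentConfig,
                   rng: np.random.Generator) -> ImageSample:
    """Return an augmented copy: deterministic flip when ``config.hflip`` is
    set, then Gaussian noise and a contrast factor drawn from ``rng``,
    clipped to [0, 1]; mask flipped alongside the image, noise applied to
    the image only."""
    image = sample.image.copy()
    mask = sample.mask.copy()
    if config.hflip:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    lo, hi = config.contrast_range
    if lo != 1.0 or hi != 1.0:
        image = image * rng.uniform(lo, hi)
    if config.gaussian_sigma > 0:
        image = image + rng.normal(0.0, config.gaussian_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return ImageSample(image=image, mask=mask,
                       source_id=sample.source_id + "+aug", augmented=True)


def expand_dataset(samples: list[ImageSample], config: AugmentConfig,
                   seed: int = 0) -> list[ImageSample]:
    """Expand a dataset to ``expansion_factor`` times its size: originals
    verbatim plus seeded augmented copies (each copy flips with probability
    1/2 when flipping is enabled)."""
    rng = np.random.default_rng(seed)
    out = list(samples)
    for _ in range(config.expansion_factor - 1):
        for s in samples:
            per_copy = replace(config,
                               hflip=bool(config.hflip and rng.random() < 0.5))
            out.append(augment_sample(s, per_copy, rng))
    return out


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate at an epoch: cosine annealing from ``lr_init`` down to
    ``lr_init * lr_final_factor`` over ``max_epochs``, with an optional
    linear warmup prefix."""
    if not 0 <= epoch <= config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs}]")
    lr_max = config.lr_init
    lr_min = config.lr_init * config.lr_final_factor
    warm = config.warmup_epochs if config.schedule == "cosine+warmup" else 0
    if warm and epoch < warm:
        return lr_max * (epoch + 1) / warm
    t = epoch - warm
    T = max(config.max_epochs - warm, 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t / T))


def _batch_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    masks = np.stack([s.mask for s in samples]).astype(np.int64)
    return images, masks


def _evaluate(model: StackedModel, samples: list[ImageSample],
              loss_cfg: CombinedLossConfig, n_classes: int,
              batch_size: int) -> tuple[float, float]:
    """Mean combined loss and mean overall Dice on a sample list."""
    model.eval()
    losses, dices = [], []
    with no_grad():
        for i in range(0, len(samples), batch_size):
            chunk = samples[i:i + batch_size]
            images, masks = _batch_arrays(chunk)
            probs = model(Tensor(images))[-1]
            losses.append(float(combined_loss(masks, probs.data, loss_cfg))
                          * len(chunk))
            preds = np.argmax(probs.data, axis=1)
            for m, p in zip(masks, preds):
                dices.append(dice_score_image(m, p, n_classes)[1])
    model.train()
    return sum(losses) / len(samples), float(np.mean(dices))


def _train_phase(model: StackedModel, params, train_samples, val_samples,
                 config: TrainConfig, loss_on_stacks: list[int],
                 log: list[dict], phase: str) -> None:
    """One optimisation phase: minimise the combined loss on the listed
    stack outputs, early-stopping on validation combined loss."""
    n_classes = model.spec.n_classes
    opt = Adam(params, lr=config.lr_init, clip_norm=config.clip_norm)
    rng = np.random.default_rng(config.seed + 1)
    best_loss = np.inf
    best_state = None
    stall = 0
    for epoch in range(config.max_epochs):
        opt.lr = lr_at(epoch, config)
        order = rng.permutation(len(train_samples))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_samples[j] for j in order[i:i + config.batch_size]]
            images, masks = _batch_arrays(chunk)
            outputs = model(Tensor(images))
            loss = None
            for k in loss_on_stacks:
                weight = config.aux_weight if (k < loss_on_stacks[-1]) else 1.0
                term = combined_loss(masks, outputs[k], config.loss) * weight
                loss = term if loss is None else loss + term
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(chunk)
            seen += len(chunk)
        val_loss, val_dice = _evaluate(model, val_samples, config.loss,
                                       n_classes, config.batch_size)
        log.append({"phase": phase, "epoch": epoch,
                    "train_loss": epoch_loss / seen, "val_loss": val_loss,
                    "val_dice": val_dice, "lr": opt.lr})
        if val_loss < best_loss - 1e-7:
            best_loss = val_loss
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)


def train(spec: StackedModelSpec, train_samples: list[ImageSample],
          val_samples: list[ImageSample],
          config: TrainConfig) -> tuple[StackedModel, pd.DataFrame]:
    """Train a stacked model, returning the best-validation model and a
    per-epoch log (train loss, val loss, val overall Dice, lr).

    Joint mode minimises ``aux_weight * L(stack-1 output) + L(final
    output)`` end to end; sequential mode trains stack 1 to early stop,
    freezes it, then trains stack 2 on its outputs.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    model = build_stacked(spec, seed=config.seed)
    model.train()
    log: list[dict] = []
    if config.stack_mode == "joint" or model.n_stacks == 1:
        stacks = list(range(model.n_stacks))
        _train_phase(model, model.parameters(), train_samples, val_samples,
                     config, stacks, log, phase="joint")
    else:
        for k in range(model.n_stacks):
            _train_phase(model, model.stack_parameters(k), train_samples,
                         val_samples, config, [k], log, phase=f"stack{k + 1}")
    return model, pd.DataFrame(log)


def cross_validate(samples: list[ImageSample], spec: StackedModelSpec,
                   config: TrainConfig, k: int = 4
                   ) -> tuple[CVSummary, list[pd.DataFrame]]:
    """k-fold cross-validation: one training run per fold on identical spec
    and config; fold scores are the held-out overall Dice of the
    best-validation model, aggregated as mean ± sample std."""
    folds = kfold_split(samples, k, seed=config.seed)
    scores, logs = [], []
    for fold_train, fold_val in folds:
        model, log = train(spec, fold_train, fold_val, config)
        _, dice = _evaluate(model, fold_val, config.loss,
                            spec.n_classes, config.batch_size)
        scores.append(dice)
        logs.append(log)
    return cv_aggregate(scores), logs


def random_search(space: SearchSpace, evaluate, seed: int | None = None
                  ) -> list[tuple[float, dict]]:
    """Draw ``budget`` configurations uniformly (with replacement) from the
    grids, score each with ``evaluate(config) -> float``, and return
    (score, config) pairs sorted by score descending."""
    rng = np.random.default_rng(space.seed if seed is None else seed)
    keys = sorted(space.grids)
    trials = []
    for _ in range(space.budget):
        cfg = {k: space.grids[k][int(rng.integers(len(space.grids[k])))]
               for k in keys}
        trials.append((float(evaluate(cfg)), cfg))
    trials.sort(key=lambda t: t[0], reverse=True)
    return trials
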