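"""scikit-learn-style estimator facade over the stacked segmenter.

`StackedSegmenter` exposes the full pipeline — model construction,
training protocol, prediction — through the familiar
``fit(X, y) / predict(X) / score(X, y)`` API so it composes with sklearn
model selection.  ``X`` is an ``(n, H, W)`` stack of grayscale images in
[0, 1] and ``y`` the matching ``(n, H, W)`` integer label masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .losses import CombinedLossConfig
from .metrics import dice_score_image
from .network import default_spec, predict_masks
from .schema import ImageSample, split_dataset
from .training import TrainConfig, train


class StackedSegmenter(BaseEstimator):
    """Multistage stacked encoder–decoder semantic segmenter.

    Parameters
    ----------
    n_stacks : 1 for a single encoder–decoder, 2 (default) for the
        refine/denoise composition.
    encoder, encoder2 : registry names of the per-stack backbones.
    n_classes : number of output classes; inferred from ``y`` when None.
    coupling : how stack k+1 receives stack k's output
        ("image+probs", "probs_only", "logits").
    stack_mode : "joint" (end-to-end, auxiliary loss on stack 1) or
        "sequential".
    val_fraction : share of ``fit`` data held out for early stopping.

    Attributes (after fit)
    ----------------------
    model_ : the trained :class:`~octostack.network.StackedModel`.
    log_ : per-epoch training log (DataFrame).
    n_classes_ : resolved class count.
    """

    def __init__(self, n_stacks: int = 2, encoder: str = "tiny",
                 encoder2: str | None = None, n_classes: int | None = None,
                 coupling: str = "image+probs", upsample_mode: str = "bilinear",
                 lr_init: float = 0.001, batch_size: int = 32,
                 max_epochs: int = 75, early_stop_patience: int = 10,
                 stack_mode: str = "joint", aux_weight: float = 0.4,
                 val_fraction: float = 0.2, seed: int = 0):
        self.n_stacks = n_stacks
        self.encoder = encoder
        self.encoder2 = encoder2
        self.n_classes = n_classes
        self.coupling = coupling
        self.upsample_mode = upsample_mode
        self.lr_init = lr_init
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.stack_mode = stack_mode
        self.aux_weight = aux_weight
        self.val_fraction = val_fraction
        self.seed = seed

    def _to_samples(self, X, y) -> list[ImageSample]:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X and y must both be (n, H, W)")
        return [ImageSample(image=xi, mask=yi, source_id=f"sample-{i}")
                for i, (xi, yi) in enumerate(zip(X, y))]

    def fit(self, X, y):
        samples = self._to_samples(X, y)
        self.n_classes_ = int(self.n_classes if self.n_classes is not None
                              else np.asarray(y).max() + 1)
        spec = default_spec(self.n_classes_, n_stacks=self.n_stacks,
                            encoder=self.encoder, encoder2=self.encoder2,
                            coupling=self.coupling,
                            upsample_mode=self.upsample_mode)
        config = TrainConfig(lr_init=self.lr_init, batch_size=self.batch_size,
                             max_epochs=self.max_epochs,
                             early_stop_patience=self.early_stop_patience,
                             loss=CombinedLossConfig(),
                             stack_mode=self.stack_mode,
                             aux_weight=self.aux_weight, seed=self.seed)
        frac = float(self.val_fraction)
        split = split_dataset(samples, (1.0 - frac, frac, 0.0), seed=self.seed)
        self.model_, self.log_ = train(spec, split.train, split.val, config)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_masks(self.model_, np.asarray(X, dtype=np.float32))

    def predict_proba(self, X) -> np.ndarray:
        """(n, C, H, W) class probabilities from the final stack."""
        self._check_fitted()
        from ._tensor import Tensor, no_grad
        from .network import pad_to_stride
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        padded, (h, w) = pad_to_stride(X)
        self.model_.eval()
        out = []
        with no_grad():
            for i in range(0, len(padded), 8):
                probs = self.model_(Tensor(padded[i:i + 8, None]))[-1]
                out.append(probs.data)
        return np.concatenate(out)[:, :, :h, :w]

    def score(self, X, y) -> float:
        """Mean overall Dice over the images."""
        preds = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([
            dice_score_image(gt, pr, self.n_classes_)[1]
            for gt, pr in zip(y, preds)]))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
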