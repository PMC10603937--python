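# octostack

Multistage stacked encoder–decoder segmentation of retinal layers in
optical-coherence-tomography (OCT) B-scans, with a synthetic layered-phantom
generator so the whole pipeline is testable end to end without clinical data.

## Who this is for

Researchers working on OCT retinal-layer analysis who want a compact,
dependency-light reference implementation of a stacked attention U-Net
segmentation system: pluggable pyramid encoders with spatial attention, an
attention U-Net decoder built around concatenation fusion, a two-stack
refine/denoise composition, the Dice + Lovász-Softmax + Tversky compound
loss, and the full training/evaluation protocol (Adam, cosine annealing,
early stopping, k-fold cross-validation, random search).

The network and its training run on a small numpy reverse-mode autodiff core
included in the package — no GPU and no deep-learning framework required.
Built-in `TinyEncoder` backbones keep a two-stack model near 0.2 M
parameters so CPU training on phantoms takes minutes.

## The model

Each **stack** is one encoder–decoder pair. The encoder produces a feature
pyramid at strides 2–32; every stage applies a spatial-attention gate
`sigmoid(conv7x7([channel-mean; channel-max]))`. The decoder fuses the
primary map *x* with each skip map through concatenation and a 1×1
projection back to *x*'s channel count,

```
x' = Conv1x1(Cx + Cskip -> Cx)([x, skip])
```

applies spatial attention **before** each ×2 upsampling step, and ends in a
1×1 head producing C-class logits at input resolution. Stack 2 re-encodes
the original image concatenated with stack 1's softmax output, acting as a
learned denoiser/refiner of the first segmentation.

Training minimises the fixed-weight compound loss

```
L = 0.5 · Dice_multiclass + 0.3 · Lovász-Softmax + 0.2 · Tversky(α, β)
```

with soft set sizes, α = β = 0.5 by default (Tversky then reduces exactly to
Dice), and the Lovász-Softmax term computed by the standard sorted-error
Jaccard-extension algorithm. Evaluation reports hard per-class Sørensen–Dice
scores, per-image and aggregated tables, and cross-validated mean ± std.

## Worked example

```python
import numpy as np
from octostack import PhantomConfig, StackedSegmenter, generate_dataset

cfg = PhantomConfig(width=64, height=64, n_layers=4)   # 5 classes with background
samples = generate_dataset(80, cfg, seed=0)
X = np.stack([s.image for s in samples])
y = np.stack([s.mask for s in samples])

est = StackedSegmenter(n_stacks=1, max_epochs=20, batch_size=8, seed=0)
est.fit(X[:64], y[:64])
print(f"held-out mean Dice: {est.score(X[64:], y[64:]):.3f}")
```

Output:

```
held-out mean Dice: 0.843
```

i.e. on held-out moderate-noise phantoms the single-stack model recovers the
layered anatomy with a mean multiclass Dice of about 0.84 after 20 epochs of
CPU training (the estimator itself holds out a fifth of the fitted data for
early stopping). The same pipeline is scriptable from the shell:

```bash
octostack phantom --n 20 --seed 1 --out data/
octostack train --config config.yaml --seed 1 --out run/
octostack segment --model run/model.npz --images data/ --out seg/
octostack evaluate --pred seg/ --gt data/
```

## Layout

- `src/octostack/schema.py` — label schemes, samples, one-hot, splits
- `src/octostack/phantom.py` — synthetic layered OCT phantoms
- `src/octostack/losses.py` — Dice / Lovász-Softmax / Tversky / combined
- `src/octostack/metrics.py` — Dice reports, cross-validation summaries
- `src/octostack/network.py` — encoders, attention fusion, decoder, stacking
- `src/octostack/training.py` — augmentation, schedule, training loop, CV, search
- `src/octostack/estimator.py` — sklearn-style `StackedSegmenter`
- `src/octostack/io.py`, `cli.py` — file formats, overlays, `octostack` CLI
- `src/octostack/_tensor.py`, `_layers.py` — numpy autodiff core and layers
- `docs/methods.md` — model, assumptions, parameter choices, limitations
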