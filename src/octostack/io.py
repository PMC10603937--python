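"""File I/O and rendering: grayscale images, indexed-PNG label masks with an
embedded palette, scheme sidecars, color overlays, reports, checkpoints,
and run manifests.

Masks round-trip losslessly: they are written as single-channel palettised
PNGs whose palette comes from the :class:`~octostack.schema.LabelScheme`,
with a JSON sidecar naming the classes so a mask directory is
self-describing.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .metrics import DiceReport
from .network import StackedModel, StackedModelSpec, build_stacked
from .schema import ImageSample, LabelScheme, make_label_scheme

SCHEME_SIDECAR = "scheme.json"


def save_image(path, image: np.ndarray) -> None:
    """Write a [0,1] grayscale image as 8-bit PNG (or TIFF by extension)."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF (8- or 16-bit) normalised to [0,1]."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def save_mask(path, mask: np.ndarray, scheme: LabelScheme) -> None:
    """Write an integer label mask as an indexed PNG with the scheme palette."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask labels must fit in one byte")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for rgb in scheme.palette:
        palette.extend(rgb)
    img.putpalette(palette)
    img.save(path)


def load_mask(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError(f"expected an indexed or 8-bit mask PNG, got {img.mode}")
    return np.asarray(img).astype(np.int64)


def save_scheme(directory, scheme: LabelScheme) -> Path:
    path = Path(directory) / SCHEME_SIDECAR
    payload = {"names": list(scheme.names),
               "palette": [list(rgb) for rgb in scheme.palette]}
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_scheme(directory) -> LabelScheme:
    path = Path(directory) / SCHEME_SIDECAR
    payload = json.loads(path.read_text())
    return make_label_scheme(payload["names"],
                             [tuple(rgb) for rgb in payload["palette"]])


def save_dataset(directory, samples: list[ImageSample],
                 scheme: LabelScheme) -> list[tuple[Path, Path]]:
    """Write image/mask pairs (img_XXXX.png / mask_XXXX.png) plus sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_scheme(directory, scheme)
    paths = []
    for i, s in enumerate(samples):
        ip = directory / f"img_{i:04d}.png"
        mp = directory / f"mask_{i:04d}.png"
        save_image(ip, s.image)
        save_mask(mp, s.mask, scheme)
        paths.append((ip, mp))
    return paths


def load_dataset(directory) -> tuple[list[ImageSample], LabelScheme]:
    directory = Path(directory)
    scheme = load_scheme(directory)
    samples = []
    for ip in sorted(directory.glob("img_*.png")):
        mp = directory / ip.name.replace("img_", "mask_")
        samples.append(ImageSample(image=load_image(ip), mask=load_mask(mp),
                                   source_id=ip.stem))
    return samples, scheme


def render_overlay(image: np.ndarray, mask: np.ndarray, scheme: LabelScheme,
                   alpha: float = 0.5) -> np.ndarray:
    """Blend the grayscale image with per-class palette colors.

    Background (class 0) stays fully transparent; returns an (H, W, 3)
    uint8 RGB image.  ``alpha=0`` reproduces the grayscale image as RGB,
    ``alpha=1`` paints labeled regions in solid palette color.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    if mask.size and (mask.min() < 0 or mask.max() >= scheme.C):
        raise ValueError("mask labels outside the scheme")
    gray = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    out = np.stack([gray] * 3, axis=-1).astype(np.float64)
    palette = np.asarray(scheme.palette, dtype=np.float64)
    colors = palette[mask]
    labeled = (mask > 0)[..., None]
    out = np.where(labeled, (1 - alpha) * out + alpha * colors, out)
    return out.round().astype(np.uint8)


def save_checkpoint(path, model: StackedModel) -> None:
    """Serialise weights + an embedded JSON of the model spec (.npz)."""
    state = model.state_dict()
    spec_json = json.dumps(_spec_to_dict(model.spec))
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> StackedModel:
    with np.load(path) as data:
        spec_json = bytes(data["__spec__"]).decode()
        spec = _spec_from_dict(json.loads(spec_json))
        model = build_stacked(spec, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model


def _spec_to_dict(spec: StackedModelSpec) -> dict:
    return {"coupling": spec.coupling,
            "detach_coupling": spec.detach_coupling,
            "residual_refine": spec.residual_refine,
            "stacks": [[asdict(e), asdict(d)] for e, d in spec.stacks]}


def _spec_from_dict(d: dict) -> StackedModelSpec:
    from .network import DecoderSpec, EncoderSpec
    stacks = []
    for e, dec in d["stacks"]:
        e["stage_channels"] = tuple(e.get("stage_channels", ()))
        dec["channels"] = tuple(dec["channels"])
        stacks.append((EncoderSpec(**e), DecoderSpec(**dec)))
    return StackedModelSpec(stacks=tuple(stacks), coupling=d["coupling"],
                            detach_coupling=d.get("detach_coupling", True),
                            residual_refine=d.get("residual_refine", True))


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, version, checksums."""

    command: str
    seed: int
    version: str
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def checksum_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
    try:
        with os.fdopen(fd, "wb") as f:
            f.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(predictions: list[tuple[str, np.ndarray, np.ndarray]],
                  report: DiceReport | None, manifest: RunManifest,
                  out_dir, scheme: LabelScheme, alpha: float = 0.5) -> list[Path]:
    """Write predicted masks, overlays, report CSV/JSON, and the manifest.

    ``predictions`` holds ``(image_id, image, predicted_mask)`` triples.
    Re-running with identical inputs overwrites atomically and
    byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for img_id, image, mask in predictions:
        mp = out_dir / f"{img_id}_mask.png"
        save_mask(mp, mask, scheme)
        op = out_dir / f"{img_id}_overlay.png"
        overlay = render_overlay(image, mask, scheme, alpha=alpha)
        Image.fromarray(overlay, mode="RGB").save(op)
        paths.extend([mp, op])
    if report is not None:
        csv_path = out_dir / "report.csv"
        report.to_frame().to_csv(csv_path)
        json_path = out_dir / "report.json"
        _atomic_write_bytes(json_path, json.dumps({
            "per_class": {str(k): v for k, v in report.per_class.items()},
            "overall": report.overall,
            "n_images": report.n_images}, indent=2).encode())
        paths.extend([csv_path, json_path])
    manifest.outputs = [str(p) for p in paths]
    mpath = out_dir / "manifest.json"
    manifest.save(mpath)
    paths.append(mpath)
    return paths
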