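"""Dataset reading, resizing and augmentation.

Images are resized bilinearly and scaled to [0, 1]; masks are resized
with nearest-neighbour interpolation so the label set {0, 1} is
preserved exactly.  Augmentation applies the same lattice-bijective
transform (flips and right-angle rotations) to image and mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import InputError

__all__ = ["load_pair", "augment", "LesionDataset", "channel_stats"]


def load_pair(image_path, mask_path, size: tuple[int, int] | None = (256, 256)):
    """Load an aligned (image, mask) pair.

    Returns image (3, H, W) float in [0, 1] and mask (1, H, W) float in
    {0, 1}.  ``size`` is (H, W); None keeps native resolution.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for path in (image_path, mask_path):
        if not path.exists():
            raise InputError(f"missing file: {path}")
    try:
        img = Image.open(image_path).convert("RGB")
        msk = Image.open(mask_path).convert("L")
    except Exception as exc:  # pillow raises a zoo of types for corrupt files
        raise InputError(f"could not read image pair: {exc}") from exc
    raw = np.asarray(msk)
    # tolerate mild anti-aliasing in stored masks but reject non-binary labels
    off = ~np.isin(raw, (0, 255))
    if off.mean() > 0.01:
        raise InputError(
            f"mask {mask_path} is not binary: {off.mean():.1%} of pixels "
            "outside {0, 255}"
        )
    if size is not None:
        h, w = size
        img = img.resize((w, h), Image.BILINEAR)
        msk = msk.resize((w, h), Image.NEAREST)
    image = np.asarray(img, dtype=np.float64).transpose(2, 0, 1) / 255.0
    mask = (np.asarray(msk, dtype=np.float64) >= 128.0).astype(np.float64)[None]
    return image, mask


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator):
    """Random flip/right-angle rotation, identically applied to both.

    All transforms are lattice bijections, so the mask's positive-pixel
    count is preserved exactly.
    """
    if rng.random() < 0.5:
        image, mask = image[:, :, ::-1], mask[:, :, ::-1]
    if rng.random() < 0.5:
        image, mask = image[:, ::-1, :], mask[:, ::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        image = np.rot90(image, k, axes=(1, 2))
        mask = np.rot90(mask, k, axes=(1, 2))
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over a stack of (N, 3, H, W) images."""
    mean = images.mean(axis=(0, 2, 3))
    std = images.std(axis=(0, 2, 3))
    return mean, np.maximum(std, 1e-6)


class LesionDataset:
    """Image/mask pairs in the on-disk layout written by the generator
    (``images/*.png`` with ``masks/<stem>_mask.png``), with or without a
    manifest."""

    def __init__(self, root, size: tuple[int, int] | None = (256, 256)):
        self.root = Path(root)
        self.size = size
        manifest = self.root / "manifest.json"
        if manifest.exists():
            entries = json.loads(manifest.read_text())["entries"]
            self.pairs = [(self.root / e["image"], self.root / e["mask"]) for e in entries]
        else:
            images = sorted((self.root / "images").glob("*.png")) if (
                self.root / "images").is_dir() else []
            self.pairs = [
                (img, self.root / "masks" / f"{img.stem}_mask.png") for img in images
            ]
        self.pairs = [(i, m) for i, m in self.pairs if i.exists() and m.exists()]

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int):
        return load_pair(*self.pairs[i], size=self.size)

    def load_all(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            raise InputError(f"no image/mask pairs found under {self.root}")
        images, masks = zip(*(self[i] for i in range(len(self))))
        return np.stack(images), np.stack(masks)
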