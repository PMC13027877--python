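"""Procedural dermoscopy-like image/mask pairs.

Each image is a skin-tone background with smooth low-frequency texture
containing a single star-convex darker lesion (an ellipse perturbed by
random radial harmonics), blended with a Gaussian-blurred boundary, with
optional dark hair strokes drawn over the top.  The mask is the exact
pre-blur lesion region, so hair and blur act as nuisances exactly as in
curated dermoscopy ground truth.

Three challenge regimes are exposed: ``complex_background`` (hair and
strong texture), ``blurred_boundary`` and ``low_contrast``, alongside the
easy ``sharp`` default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import ConfigurationError, GenerationError

__all__ = ["SynthParams", "REGIMES", "generate_lesion_image", "generate_split"]

_MAX_REJECTS = 60

# base skin and lesion tones (RGB in [0,1]); jittered per image
_SKIN_TONES = np.array([
    [0.87, 0.72, 0.63],
    [0.92, 0.78, 0.68],
    [0.80, 0.62, 0.52],
    [0.73, 0.55, 0.45],
])
_LESION_DARKENING = np.array([0.55, 0.65, 0.70])  # stronger in red/green
_HAIR_COLOR = np.array([0.15, 0.10, 0.08])


@dataclass(frozen=True)
class SynthParams:
    image_size: tuple[int, int] = (256, 256)
    lesion_area_fraction: tuple[float, float] = (0.05, 0.35)
    contrast: float = 0.8
    boundary_blur_sigma: float = 1.0
    hair_count: int = 0
    hair_width: int = 2
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 0.9):
            raise ConfigurationError("lesion_area_fraction must satisfy 0 < min <= max < 0.9")
        if not (0.0 <= self.contrast <= 1.0):
            raise ConfigurationError("contrast must lie in [0, 1]")
        if min(self.image_size) < 8:
            raise ConfigurationError("image extents must be >= 8")
        if self.hair_count < 0 or self.hair_width < 1:
            raise ConfigurationError("hair parameters out of range")


REGIMES: dict[str, dict] = {
    "sharp": {},
    "complex_background": {"hair_count": 6, "noise_sigma": 0.04},
    "blurred_boundary": {"boundary_blur_sigma": 6.0},
    "low_contrast": {"contrast": 0.15},
}


def params_for_regime(base: SynthParams, regime: str) -> SynthParams:
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    return dataclasses.replace(base, **REGIMES[regime])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _lesion_mask(rng: np.random.Generator, H: int, W: int,
                 area_range: tuple[float, float]) -> np.ndarray:
    """Star-convex region: r(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k)),
    harmonics k in 2..6 with |a_k| <= 0.25 in total, rejected until the mask
    coverage lands inside ``area_range``."""
    lo, hi = area_range
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(_MAX_REJECTS):
        target = rng.uniform(lo, hi)
        cy = rng.uniform(0.35 * H, 0.65 * H)
        cx = rng.uniform(0.35 * W, 0.65 * W)
        r0 = np.sqrt(target * H * W / np.pi)
        amps = rng.uniform(-0.05, 0.05, 5)
        total = np.abs(amps).sum()
        if total > 0.25:
            amps *= 0.25 / total
        phases = rng.uniform(0, 2 * np.pi, 5)
        aspect = rng.uniform(0.7, 1.3)
        dy, dx = (yy - cy) * aspect, xx - cx
        theta = np.arctan2(dy, dx)
        radius = np.hypot(dy, dx)
        boundary = r0 * (1.0 + sum(
            a * np.cos(k * theta + p) for k, a, p in zip(range(2, 7), amps, phases)
        ))
        mask = radius <= boundary
        frac = mask.mean()
        if lo <= frac <= hi and mask.any():
            labels, n = ndimage.label(mask)
            if n == 1:
                return mask
    raise GenerationError(
        f"could not place a lesion with area fraction in [{lo}, {hi}] "
        f"after {_MAX_REJECTS} attempts"
    )


def _hair_strokes(rng: np.random.Generator, H: int, W: int, count: int,
                  width: int) -> np.ndarray:
    """Boolean canvas of quadratic Bezier strokes of the given width."""
    canvas = np.zeros((H, W), dtype=bool)
    for _ in range(count):
        pts = rng.uniform([-0.2 * H, -0.2 * W], [1.2 * H, 1.2 * W], (3, 2))
        t = np.linspace(0.0, 1.0, 4 * (H + W))[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t ** 2 * pts[2])
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < H) & (ij[:, 1] >= 0) & (ij[:, 1] < W)
        canvas[ij[keep, 0], ij[keep, 1]] = True
    if canvas.any() and width > 1:
        canvas = ndimage.binary_dilation(canvas, iterations=width - 1)
    return canvas


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def generate_lesion_image(p: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, mask) pair.

    Returns the image as float (H, W, 3) in [0, 1] and the mask as a
    boolean (H, W) array.  The same seed yields bitwise-identical output.
    """
    rng = np.random.default_rng(p.seed)
    H, W = p.image_size

    skin = _SKIN_TONES[rng.integers(len(_SKIN_TONES))] + rng.normal(0, 0.02, 3)
    image = np.ones((H, W, 3)) * skin
    # smooth low-frequency texture
    texture = ndimage.gaussian_filter(rng.normal(0, 1.0, (H, W)), sigma=0.08 * min(H, W))
    image += 0.25 * texture[:, :, None] * np.array([1.0, 0.9, 0.8])

    mask = _lesion_mask(rng, H, W, p.lesion_area_fraction)

    # lesion tone: darker than skin in proportion to the contrast setting
    separation = 0.12 + 0.5 * p.contrast
    lesion_tone = np.clip(skin - separation * _LESION_DARKENING, 0.02, 1.0)
    # internal texture so lesions are not flat
    inner = ndimage.gaussian_filter(rng.normal(0, 1.0, (H, W)), sigma=0.03 * min(H, W))
    lesion_layer = lesion_tone + 0.05 * inner[:, :, None]

    alpha = ndimage.gaussian_filter(mask.astype(float), sigma=max(p.boundary_blur_sigma, 1e-6))
    image = (1.0 - alpha[:, :, None]) * image + alpha[:, :, None] * lesion_layer

    if p.hair_count:
        hair = _hair_strokes(rng, H, W, p.hair_count, p.hair_width)
        image[hair] = 0.2 * image[hair] + 0.8 * _HAIR_COLOR

    if p.noise_sigma:
        image += rng.normal(0, p.noise_sigma, image.shape)

    return np.clip(image, 0.0, 1.0), mask


def _save_pair(image: np.ndarray, mask: np.ndarray, img_path: Path, mask_path: Path) -> None:
    Image.fromarray((image * 255).round().astype(np.uint8)).save(img_path)
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(mask_path)


def generate_split(n: int, p: SynthParams, out_dir, regime: str | None = None) -> dict:
    """Write ``n`` image/mask PNG pairs plus a JSON manifest.

    Layout: ``out_dir/images/<stem>.png`` and ``out_dir/masks/<stem>_mask.png``.
    When ``regime`` is None the four regimes are cycled so a split covers
    all challenge conditions.  Per-image seeds are derived from ``p.seed``
    and recorded in the manifest, so any row can be regenerated bit-exactly.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    regimes = list(REGIMES) if regime is None else [regime]
    entries = []
    for i in range(n):
        reg = regimes[i % len(regimes)]
        pi = dataclasses.replace(params_for_regime(p, reg), seed=p.seed + 10_000 * i)
        image, mask = generate_lesion_image(pi)
        stem = f"synth_{i:05d}"
        _save_pair(image, mask, out_dir / "images" / f"{stem}.png",
                   out_dir / "masks" / f"{stem}_mask.png")
        entries.append({
            "image": f"images/{stem}.png",
            "mask": f"masks/{stem}_mask.png",
            "seed": pi.seed,
            "regime": reg,
            "area_fraction": float(mask.mean()),
        })
    manifest = {"n": n, "base_seed": p.seed, "image_size": list(p.image_size),
                "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
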