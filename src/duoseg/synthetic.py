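"""Seeded generator of ultrasound-like phantoms with paired ground-truth masks.

Real clinical ultrasound is hard to segment for reasons that are easy to state
generatively: lesions are darker than their surroundings by only a small
intensity margin, the whole field is covered in multiplicative speckle,
boundaries are blurred by the point-spread function, and an image may contain
several lesions (plus occasional acoustic shadowing below strong reflectors).
The generator emulates exactly those failure modes:

1. a smooth background intensity field (base level plus a low-frequency
   Gaussian random field),
2. 1-3 elliptical lesions (random centre/axes/rotation, overlap allowed)
   darkened by a per-image ``contrast`` drawn from a configured range,
3. Gaussian blur of the *clean* field (boundary blur, applied before noise),
4. optional vertical shadow band below a lesion,
5. multiplicative gamma speckle with mean 1 (shape k; variance 1/k), then
   clipping to [0, 1].

Everything is driven by a single ``numpy.random.Generator``, so a dataset is
byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError

__all__ = ["PhantomSpec", "generate_mask", "render_image", "make_phantom", "make_dataset"]


@dataclass
class PhantomSpec:
    """Generation parameters; ranges are sampled per image/lesion."""

    image_size: int = 256
    n_lesions: tuple = (1, 3)  # inclusive range
    lesion_axes: tuple = (8, 40)  # semi-axis range, pixels
    contrast: tuple = (0.1, 0.35)  # mean intensity drop inside lesions
    speckle_shape: float = 4.0  # gamma shape k (variance 1/k)
    blur_sigma: float = 1.0  # boundary blur, pixels
    shadow_prob: float = 0.3
    background: float = 0.6

    def __post_init__(self):
        if self.lesion_axes[0] < 3:
            raise ValueError("lesion semi-axes must be at least 3 px")
        if not (1 <= self.n_lesions[0] <= self.n_lesions[1] <= 3):
            raise ValueError("n_lesions range must lie within [1, 3]")
        if self.contrast[0] < 0:
            raise ValueError("contrast must be positive")

    def scaled(self, image_size: int) -> "PhantomSpec":
        """Same spec with geometry scaled to another image size."""
        f = image_size / self.image_size
        axes = (max(3, round(self.lesion_axes[0] * f)), max(4, round(self.lesion_axes[1] * f)))
        return PhantomSpec(
            image_size=image_size,
            n_lesions=self.n_lesions,
            lesion_axes=axes,
            contrast=self.contrast,
            speckle_shape=self.speckle_shape,
            blur_sigma=self.blur_sigma,
            shadow_prob=self.shadow_prob,
            background=self.background,
        )


def _draw_ellipse(size: int, center, axes, rotation: float) -> np.ndarray:
    """Filled ellipse: pixels with (u/a)^2 + (v/b)^2 <= 1 in rotated coordinates."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    u = np.cos(rotation) * dy + np.sin(rotation) * dx
    v = -np.sin(rotation) * dy + np.cos(rotation) * dx
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_mask(spec: PhantomSpec, rng: np.random.Generator, max_tries: int = 50) -> np.ndarray:
    """Union of 1-3 filled ellipses, fully inside the frame; values {0,1}."""
    size = spec.image_size
    n = int(rng.integers(spec.n_lesions[0], spec.n_lesions[1] + 1))
    mask = np.zeros((size, size), dtype=bool)
    lo, hi = spec.lesion_axes
    for _ in range(n):
        placed = False
        for _ in range(max_tries):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            margin = int(np.ceil(max(a, b))) + 1
            if 2 * margin >= size:
                continue
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            rot = rng.uniform(0, np.pi)
            mask |= _draw_ellipse(size, (cy, cx), (a, b), rot)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place a lesion with axes in [{lo},{hi}] on a {size}px frame"
            )
    return mask.astype(np.uint8)


def render_image(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Render a speckled grayscale image in [0,1] for a given lesion mask."""
    size = spec.image_size
    field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 8)
    clean = spec.background + 0.05 * field / max(field.std(), 1e-9)
    contrast = rng.uniform(*spec.contrast)
    clean = clean - contrast * mask.astype(float)

    if rng.uniform() < spec.shadow_prob and mask.any():
        cols = np.where(mask.any(axis=0))[0]
        c0, c1 = cols.min(), cols.max()
        rows = np.where(mask.any(axis=1))[0]
        depth = rows.max()
        fade = np.linspace(0.75, 0.5, size - depth) if depth < size else np.empty(0)
        clean[depth:, c0 : c1 + 1] *= fade[:, None]

    if spec.blur_sigma > 0:
        clean = ndimage.gaussian_filter(clean, sigma=spec.blur_sigma)
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, (size, size))
    return np.clip(clean * speckle, 0.0, 1.0)


def make_phantom(spec: PhantomSpec, rng: np.random.Generator):
    """Convenience: one (image, mask) pair."""
    mask = generate_mask(spec, rng)
    return render_image(mask, spec, rng), mask


def make_dataset(spec: PhantomSpec, n_images: int, out_dir, seed: int = 0) -> pd.DataFrame:
    """Write ``n_images`` phantoms as 8-bit PNGs plus a CSV manifest.

    Masks are saved as {0, 255}.  The split column assigns the first 80% of
    images to train, the next 10% to val, the rest to test.  Returns the
    manifest (columns: image_path, mask_path, split) which is also written to
    ``out_dir/manifest.csv``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_train = int(round(n_images * 0.8))
    n_val = int(round(n_images * 0.1))
    rows = []
    for i in range(n_images):
        image, mask = make_phantom(spec, rng)
        img_path = out / "images" / f"phantom_{i:04d}.png"
        mask_path = out / "masks" / f"phantom_{i:04d}_mask.png"
        iio.imwrite(img_path, np.round(image * 255).astype(np.uint8))
        iio.imwrite(mask_path, (mask * 255).astype(np.uint8))
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        rows.append({"image_path": str(img_path), "mask_path": str(mask_path), "split": split})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
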