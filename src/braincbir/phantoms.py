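"""Synthetic brain-phantom image generation.

Produces seeded, labelled 2-D grayscale phantoms that emulate the statistical
structure of clinical brain-slice collections in which several diseases share
a common anatomy: every image carries the same elliptical "brain" background
(tissue, skull rim, ventricles), while each disease class is expressed only
as a small local lesion whose position and size vary image to image.

Three lesion archetypes are provided:

* class 0 — a bright compact blob at an arbitrary intra-cranial position
  (hemorrhage-like);
* class 1 — a small blob confined to the lower midline (pituitary-like);
* class 2 — a larger, irregularly textured region (glioma-like).

Classes beyond three reuse the archetypes (``class % 3``) with a class-specific
angular offset of the allowed lesion region, so any ``n_classes >= 2`` remains
discriminable.  Two intensity regimes stand in for imaging modalities:
``m0`` renders the phantom as-is, ``m1`` applies a global intensity inversion
followed by a gamma shift (a cheap CT-vs-MR appearance proxy).

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so an identical spec reproduces the image
set bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomSpec",
    "LabeledImage",
    "generate_phantom_set",
    "background_image",
    "write_image_set",
    "read_image_set",
]

# lesion radii as a fraction of the image side; the largest (glioma-like)
# keeps the lesion below 10% of the brain area so global anatomy dominates
_LESION_RADII = {
    0: (0.055, 0.085),
    1: (0.040, 0.065),
    2: (0.060, 0.090),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image set.

    Parameters
    ----------
    image_size : int
        Pixels per side of the square images (>= 32).
    n_classes : int
        Number of disease classes (>= 2).
    n_per_class : int
        Images generated per class.
    modality_mix : float
        Fraction of each class rendered in the second intensity regime
        (``m1``); the remainder is ``m0``.  In [0, 1].
    noise_sigma : float
        Standard deviation of additive Gaussian noise, in [0, 1] intensity
        units.
    seed : int
        Seed for all randomness; identical specs give bit-identical sets.
    """

    image_size: int = 48
    n_classes: int = 3
    n_per_class: int = 50
    modality_mix: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not 0.0 <= self.modality_mix <= 1.0:
            raise ValueError(
                f"modality_mix must be in [0, 1], got {self.modality_mix}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass
class LabeledImage:
    """A single-channel phantom with its class label and modality tag.

    ``pixels`` is a float32 array in [0, 1].  ``lesion_mask`` (boolean, same
    shape) marks the pixels touched by the lesion; it exists only in memory
    for analysis and testing and is never persisted.
    """

    pixels: np.ndarray
    label: int
    modality: str
    id: str
    lesion_mask: np.ndarray | None = field(default=None, repr=False)


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.linspace(-1.0, 1.0, size, dtype=np.float64)
    return np.meshgrid(c, c, indexing="xy")


def background_image(image_size: int) -> np.ndarray:
    """The shared lesion-free anatomy: tissue ellipse, skull rim, ventricles.

    Purely a function of pixel coordinates, hence identical across every
    phantom of a set.
    """
    u, v = _grid(image_size)
    # elliptical brain, slightly taller than wide
    r = np.sqrt((u / 0.78) ** 2 + (v / 0.90) ** 2)
    img = np.full((image_size, image_size), 0.02)
    inside = r <= 1.0
    # soft radial tissue gradient
    img[inside] = 0.55 - 0.10 * r[inside] ** 2
    # bright skull rim
    img += 0.35 * np.exp(-(((r - 0.96) / 0.05) ** 2)) * (r <= 1.08)
    # two dark ventricle-like lobes near the centre
    for du in (-0.16, 0.16):
        rv = np.sqrt(((u - du) / 0.10) ** 2 + ((v + 0.10) / 0.24) ** 2)
        img -= 0.22 * np.exp(-(rv**2)) * inside
    return np.clip(img, 0.0, 1.0)


def _brain_interior(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.sqrt((u / 0.78) ** 2 + (v / 0.90) ** 2) <= 0.82


def _lesion(
    label: int, n_classes: int, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Additive lesion field and its boolean mask for one image."""
    u, v = _grid(size)
    archetype = label % 3
    lo, hi = _LESION_RADII[archetype]
    radius = rng.uniform(lo, hi) * 2.0  # to [-1,1] grid units
    # class-specific angular offset keeps labels >= 3 separable
    phase = 2.0 * math.pi * (label // 3) / max(1, math.ceil(n_classes / 3))

    if archetype == 1:
        # pituitary-like: lower midline
        cu = rng.uniform(-0.06, 0.06)
        cv = rng.uniform(0.30, 0.48)
    else:
        ang = rng.uniform(0.0, 2.0 * math.pi) + phase
        rad = rng.uniform(0.15, 0.50)
        cu, cv = rad * math.cos(ang), rad * math.sin(ang)

    d = np.sqrt((u - cu) ** 2 + (v - cv) ** 2) / radius
    envelope = np.exp(-(d**4))  # compact, soft-edged
    mask = d <= 1.4

    if archetype == 2:
        # irregular texture: a few random low-frequency sinusoids
        tex = np.zeros_like(u)
        for _ in range(4):
            kx, ky = rng.uniform(4.0, 9.0, size=2)
            ph = rng.uniform(0.0, 2.0 * math.pi)
            tex += rng.uniform(0.5, 1.0) * np.sin(kx * u + ky * v + ph)
        tex /= 4.0
        bump = (0.18 + 0.20 * tex) * envelope
    elif archetype == 1:
        bump = 0.32 * envelope
    else:
        bump = 0.38 * envelope

    # truncate exactly at the mask edge (envelope ~0.02 there) so pixels
    # outside the mask are bit-identical to the shared background
    interior = _brain_interior(u, v)
    mask &= interior
    bump = np.where(mask, bump, 0.0)
    return bump, mask


def _modality_flags(n: int, mix: float, rng: np.random.Generator) -> np.ndarray:
    n1 = int(round(mix * n))
    flags = np.zeros(n, dtype=bool)
    flags[:n1] = True
    return rng.permutation(flags)


def _apply_modality(img: np.ndarray, modality: str) -> np.ndarray:
    if modality == "m0":
        return img
    # global inversion plus gamma shift
    return np.clip(1.0 - img, 0.0, 1.0) ** 1.6


def generate_phantom_set(spec: PhantomSpec) -> list[LabeledImage]:
    """Generate ``n_classes * n_per_class`` labelled phantom images.

    Images are ordered by class, then index within class.  Lesion geometry is
    drawn per image from the seeded generator; the background is shared.
    """
    root = np.random.SeedSequence(spec.seed)
    class_seeds = root.spawn(spec.n_classes)
    bg = background_image(spec.image_size)

    images: list[LabeledImage] = []
    for label in range(spec.n_classes):
        crng = np.random.default_rng(class_seeds[label])
        flags = _modality_flags(spec.n_per_class, spec.modality_mix, crng)
        for i in range(spec.n_per_class):
            bump, mask = _lesion(label, spec.n_classes, spec.image_size, crng)
            img = np.clip(bg + bump, 0.0, 1.0)
            modality = "m1" if flags[i] else "m0"
            img = _apply_modality(img, modality)
            if spec.noise_sigma > 0:
                img = img + crng.normal(0.0, spec.noise_sigma, img.shape)
                img = np.clip(img, 0.0, 1.0)
            images.append(
                LabeledImage(
                    pixels=img.astype(np.float32),
                    label=label,
                    modality=modality,
                    id=f"c{label}_i{i:03d}",
                    lesion_mask=mask,
                )
            )
    return images


def write_image_set(images: list[LabeledImage], directory: str | Path) -> Path:
    """Write one 8-bit grayscale PNG per image plus a CSV manifest.

    Returns the manifest path.  Round-trips through :func:`read_image_set`
    with at most 1/255 per-pixel quantization error.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        fname = f"{im.id}.png"
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / fname)
        rows.append(
            {"id": im.id, "filename": fname, "label": im.label, "modality": im.modality}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=["id", "filename", "label", "modality"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_image_set(directory: str | Path) -> list[LabeledImage]:
    """Load a phantom set previously written by :func:`write_image_set`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest, dtype={"id": str, "filename": str, "modality": str})
    images = []
    for row in df.itertuples(index=False):
        arr = np.asarray(Image.open(directory / row.filename), dtype=np.float32)
        images.append(
            LabeledImage(
                pixels=arr / 255.0,
                label=int(row.label),
                modality=row.modality,
                id=row.id,
            )
        )
    return images
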