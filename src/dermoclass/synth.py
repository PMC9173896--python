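"""Synthetic two-class dermoscopic-style image generator.

Produces labeled lesion images with ground-truth masks so the full
pipeline (denoise -> segment -> featurize -> classify -> evaluate) can be
exercised and tested without any external dataset.  A lesion is a dark,
pigmented region drawn as an ellipse whose boundary radius is perturbed
by low-order sinusoids; melanoma-class images receive stronger shape
asymmetry, larger border-irregularity amplitude, and higher within-lesion
color variance than benign-class images, mirroring the ABCD criteria
(asymmetry, border, color) dermatologists use.

The background is a uniform skin tone with a low-amplitude smooth texture
so that an edge-preserving filter has structure to preserve.  Gaussian
pixel noise and salt-and-pepper corruption are applied last; the
ground-truth mask refers to the clean geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MelanomaEffect",
    "NoiseParams",
    "SynthConfig",
    "LabeledImage",
    "generate_dataset",
    "add_noise",
    "write_dataset",
]

MELANOMA = "melanoma"
BENIGN = "benign"

# Base colors in [0,1] RGB: light skin tone vs. dark pigmented lesion.
_SKIN_TONE = np.array([0.85, 0.66, 0.55])
_LESION_TONE = np.array([0.38, 0.24, 0.18])


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class MelanomaEffect:
    """Class-contrast knobs applied to melanoma-class images only.

    asymmetry_scale : >= 0, strength of odd radial harmonics that break
        the lesion's mirror symmetry.
    border_irregularity : >= 0, extra amplitude of the sinusoidal
        boundary perturbation (fraction of mean radius).
    color_variance_multiplier : >= 1, scales the within-lesion color
        jitter relative to benign lesions.
    """

    asymmetry_scale: float = 1.0
    border_irregularity: float = 0.4
    color_variance_multiplier: float = 2.5


@dataclass(frozen=True)
class NoiseParams:
    gaussian_sigma: float = 0.02
    salt_pepper_fraction: float = 0.005


@dataclass(frozen=True)
class SynthConfig:
    n_per_class: int = 50
    image_size: tuple[int, int] = (64, 64)
    lesion_area_range: tuple[float, float] = (0.08, 0.25)
    melanoma_effect: MelanomaEffect = field(default_factory=MelanomaEffect)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        lo, hi = self.lesion_area_range
        if self.n_per_class < 0:
            raise ConfigurationError("n_per_class must be >= 0")
        if h < 16 or w < 16:
            raise ConfigurationError("image_size must be at least 16x16")
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                "lesion_area_range must satisfy 0 < min < max < 1"
            )
        e = self.melanoma_effect
        if e.asymmetry_scale < 0 or e.border_irregularity < 0:
            raise ConfigurationError("effect knobs must be non-negative")
        if e.color_variance_multiplier < 1:
            raise ConfigurationError("color_variance_multiplier must be >= 1")
        if self.noise.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be >= 0")
        if not (0.0 <= self.noise.salt_pepper_fraction <= 1.0):
            raise ConfigurationError("salt_pepper_fraction must be in [0,1]")


@dataclass(frozen=True)
class LabeledImage:
    image: np.ndarray  # H x W x 3 float in [0,1]
    label: str  # "melanoma" | "benign"
    truth_mask: np.ndarray  # H x W bool


def add_noise(
    image: np.ndarray,
    gaussian_sigma: float,
    salt_pepper_fraction: float,
    seed: int,
) -> np.ndarray:
    """Corrupt an RGB image with Gaussian and salt-and-pepper noise.

    Exactly ``round(fraction * H * W)`` pixel locations are replaced by
    pure black or pure white (all three channels); the remaining pixels
    are perturbed by zero-mean Gaussian noise of the given sigma.  The
    result is clipped to [0, 1].
    """
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    if not (0.0 <= salt_pepper_fraction <= 1.0):
        raise ValueError("salt_pepper_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    out = image.astype(float).copy()

    n_sp = int(round(salt_pepper_fraction * h * w))
    flat_idx = rng.choice(h * w, size=n_sp, replace=False)
    salt = rng.random(n_sp) < 0.5

    if gaussian_sigma > 0:
        out += rng.normal(0.0, gaussian_sigma, size=out.shape)
    rows, cols = np.unravel_index(flat_idx, (h, w))
    out[rows, cols] = np.where(salt[:, None], 1.0, 0.0)
    return np.clip(out, 0.0, 1.0)


def _lesion_mask(
    shape: tuple[int, int],
    area_fraction: float,
    irregularity: float,
    asymmetry: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary lesion mask: perturbed ellipse of roughly the target area.

    The boundary radius as a function of polar angle is
    ``r(theta) = r0 * axis(theta) * (1 + sum_m a_m sin(m theta + phi_m))``
    where even harmonics carry the border-irregularity amplitude and odd
    harmonics the asymmetry.  Radii are solved from the requested area
    fraction of the unperturbed ellipse.
    """
    h, w = shape
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    # Ellipse with aspect ratio in [0.6, 1.0], random orientation.
    aspect = rng.uniform(0.6, 1.0)
    r0 = np.sqrt(area_fraction * h * w / (np.pi * aspect))
    theta0 = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ang = np.arctan2(dy, dx) - theta0
    rad = np.hypot(dy, dx)

    # Elliptical base radius per angle.
    ct, st = np.cos(ang), np.sin(ang)
    base = r0 * aspect / np.sqrt((aspect * ct) ** 2 + st**2)

    perturb = np.zeros_like(ang)
    # Even harmonics: border irregularity (symmetric scalloping).
    for m in (2, 4, 6):
        amp = irregularity * rng.uniform(0.3, 1.0) / m
        perturb += amp * np.sin(m * ang + rng.uniform(0, 2 * np.pi))
    # Odd harmonics: asymmetry (one side bulges).
    for m in (1, 3):
        amp = 0.25 * asymmetry * rng.uniform(0.5, 1.0) / m
        perturb += amp * np.sin(m * ang + rng.uniform(0, 2 * np.pi))
    # Keep the boundary radius positive.
    perturb = np.clip(perturb, -0.8, 0.8)
    boundary = base * (1.0 + perturb)
    mask = rad <= boundary
    # The perturbation shifts the enclosed area away from the sampled
    # target; rescale the radius (perturbation field fixed) until the
    # fraction is back on target.
    target = area_fraction * h * w
    for _ in range(4):
        actual = mask.sum()
        if actual == 0:
            break
        ratio = target / actual
        if 0.995 < ratio < 1.005:
            break
        boundary = boundary * np.sqrt(ratio)
        mask = rad <= boundary
    return mask


def _render(
    mask: np.ndarray,
    color_variance_multiplier: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render skin background + pigmented lesion for a given mask."""
    h, w = mask.shape
    # Smooth low-frequency skin texture: sum of a few 2-D cosines.
    yy, xx = np.mgrid[0:h, 0:w]
    texture = np.zeros((h, w))
    for _ in range(3):
        fy, fx = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        texture += np.cos(2 * np.pi * fy * yy / h + phase[0]) * np.cos(
            2 * np.pi * fx * xx / w + phase[1]
        )
    texture *= 0.015

    img = np.empty((h, w, 3))
    skin = _SKIN_TONE + rng.normal(0, 0.02, size=3)
    lesion = _LESION_TONE + rng.normal(0, 0.03, size=3)
    img[:] = skin[None, None, :] + texture[:, :, None]

    # Within-lesion pigment mottling: smooth blotches + pixel jitter,
    # both scaled by the class color-variance knob.
    n_lesion = int(mask.sum())
    blotch = np.zeros((h, w))
    for _ in range(2):
        fy, fx = rng.uniform(1.5, 4.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        blotch += np.cos(2 * np.pi * fy * yy / h + phase[0]) * np.cos(
            2 * np.pi * fx * xx / w + phase[1]
        )
    cv = 0.035 * color_variance_multiplier
    lesion_px = (
        lesion[None, :]
        + cv * blotch[mask][:, None]
        + rng.normal(0, cv, size=(n_lesion, 3))
    )
    img[mask] = lesion_px
    return np.clip(img, 0.0, 1.0)


def _generate_one(
    config: SynthConfig, label: str, rng: np.random.Generator
) -> LabeledImage:
    lo, hi = config.lesion_area_range
    area = rng.uniform(lo, hi)
    eff = config.melanoma_effect
    if label == MELANOMA:
        irregularity = 0.08 + eff.border_irregularity
        asymmetry = eff.asymmetry_scale
        cv_mult = eff.color_variance_multiplier
    else:
        irregularity = 0.08
        asymmetry = 0.0
        cv_mult = 1.0
    mask = _lesion_mask(
        config.image_size, area, irregularity, asymmetry, rng
    )
    clean = _render(mask, cv_mult, rng)
    noisy = add_noise(
        clean,
        config.noise.gaussian_sigma,
        config.noise.salt_pepper_fraction,
        seed=int(rng.integers(0, 2**31)),
    )
    return LabeledImage(image=noisy, label=label, truth_mask=mask)


def generate_dataset(config: SynthConfig) -> list[LabeledImage]:
    """Generate ``2 * n_per_class`` labeled lesion images.

    Deterministic given ``config.seed``; melanoma and benign images
    alternate so any prefix of the list stays roughly balanced.
    """
    rng = np.random.default_rng(config.seed)
    out: list[LabeledImage] = []
    for _ in range(config.n_per_class):
        out.append(_generate_one(config, MELANOMA, rng))
        out.append(_generate_one(config, BENIGN, rng))
    return out


def write_dataset(dataset: list[LabeledImage], out_dir: str | Path) -> Path:
    """Write images/masks as 8-bit PNG plus a manifest CSV.

    Returns the manifest path.  Columns: filename, label, mask_filename.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "mask_filename"])
        for i, item in enumerate(dataset):
            name = f"img_{i:04d}.png"
            mask_name = f"mask_{i:04d}.png"
            Image.fromarray(
                (item.image * 255).round().astype(np.uint8)
            ).save(out_dir / name)
            Image.fromarray(
                np.where(item.truth_mask, 255, 0).astype(np.uint8)
            ).save(out_dir / mask_name)
            writer.writerow([name, item.label, mask_name])
    return manifest


def read_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a dataset previously written by :func:`write_dataset`."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out: list[LabeledImage] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(
                Image.open(base / row["filename"]).convert("RGB"), dtype=float
            ) / 255.0
            mask = (
                np.asarray(Image.open(base / row["mask_filename"]).convert("L"))
                > 127
            )
            out.append(
                LabeledImage(image=img, label=row["label"], truth_mask=mask)
            )
    return out
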