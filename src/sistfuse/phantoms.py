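"""Seeded synthetic image pairs for developing and testing the fusion chain.

No clinical data ships with the package; these generators produce the three
kinds of input the method needs, each a pure function of its spec:

* complementary-blur pairs — one ground-truth image, each copy sharp on one
  half and Gaussian-degraded on the other, so fusion quality can be scored
  against a known composite;
* modality phantoms — shared head-like geometry rendered with CT-like
  (bright boundary, dark interior) and MRI-like (soft-tissue gradient)
  contrast, for multi-modal behaviour without any real scanner physics;
* shifted pairs — an image and a circularly shifted copy, for keypoint
  colocation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

__all__ = [
    "PhantomSpec",
    "make_complementary_blur_pair",
    "make_modality_phantom_pair",
    "make_shifted_pair",
]

SCENARIOS = ("complementary_blur", "modality_phantom", "shifted_pair")


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    seed: int = 0
    scenario: str = "complementary_blur"
    blur_sigma: float = 3.0
    n_structures: int = 6
    shift: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if min(self.size) < 32:
            raise ConfigurationError("phantom size must be at least 32x32")


def _texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise: smoothed white noise minus its coarse component."""
    noise = rng.standard_normal(shape)
    fine = gaussian_filter(noise, 1.2, mode="wrap")
    coarse = gaussian_filter(noise, 6.0, mode="wrap")
    tex = fine - coarse
    return tex / (np.abs(tex).max() + 1e-12)


def _disk_mask(shape, cy, cx, ry, rx):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _base_scene(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shapes + texture in [0, 1]; also returns the structure mask stack."""
    h, w = spec.size
    img = np.full(spec.size, 0.15)
    masks = np.zeros((spec.n_structures, h, w), dtype=bool)
    for i in range(spec.n_structures):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ry = rng.uniform(0.05, 0.18) * h
        rx = rng.uniform(0.05, 0.18) * w
        masks[i] = _disk_mask(spec.size, cy, cx, ry, rx)
        img[masks[i]] = rng.uniform(0.3, 0.95)
    img = gaussian_filter(img, 1.0, mode="wrap")
    img += 0.18 * _texture(spec.size, rng)
    return np.clip(img, 0.0, 1.0), masks


def make_complementary_blur_pair(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A, B, ground truth): A blurred on the right half, B on the left.

    Outside its degraded half each copy equals the ground truth exactly, so
    an ideal fusion recovers the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    truth, _ = _base_scene(spec, rng)
    blurred = gaussian_filter(truth, spec.blur_sigma, mode="reflect")
    half = spec.size[1] // 2
    a = truth.copy()
    a[:, half:] = blurred[:, half:]
    b = truth.copy()
    b[:, :half] = blurred[:, :half]
    return a, b, truth


def make_modality_phantom_pair(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A, B, structure masks): shared geometry, complementary contrast.

    A renders bone-like boundaries (bright skull rim, dark interior); B
    renders soft-tissue intensity gradients inside the same outline.  The
    mask stack (structures x H x W) is identical for both images.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    skull = _disk_mask(spec.size, h / 2, w / 2, 0.45 * h, 0.42 * w)
    inner = _disk_mask(spec.size, h / 2, w / 2, 0.40 * h, 0.37 * w)
    rim = skull & ~inner
    masks = [skull]
    for _ in range(spec.n_structures - 1):
        cy = rng.uniform(0.3 * h, 0.7 * h)
        cx = rng.uniform(0.3 * w, 0.7 * w)
        masks.append(_disk_mask(spec.size, cy, cx, rng.uniform(0.04, 0.12) * h,
                                rng.uniform(0.04, 0.12) * w) & inner)
    masks = np.stack(masks)

    # CT-like: bright rim, dark interior, structures faint
    a = np.full(spec.size, 0.05)
    a[inner] = 0.18
    a[rim] = 0.95
    for m in masks[1:]:
        a[m] = 0.30
    a += 0.05 * _texture(spec.size, rng)

    # MRI-like: no bright rim; graded soft tissue, structures prominent
    b = np.full(spec.size, 0.05)
    yy = np.mgrid[0:h, 0:w][0] / h
    b[inner] = 0.35 + 0.3 * yy[inner]
    for i, m in enumerate(masks[1:]):
        b[m] = 0.55 + 0.35 * ((i % 2) * 2 - 1) * 0.5 + 0.1 * (i / max(1, len(masks) - 1))
    b[rim] = 0.15
    b += 0.08 * _texture(spec.size, np.random.default_rng(spec.seed + 1))

    return np.clip(a, 0, 1), np.clip(b, 0, 1), masks


def make_shifted_pair(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """An image and its circular shift by spec.shift = (dy, dx)."""
    dy, dx = spec.shift
    if abs(dy) >= spec.size[0] or abs(dx) >= spec.size[1]:
        raise ConfigurationError(f"shift {spec.shift} exceeds image size {spec.size}")
    rng = np.random.default_rng(spec.seed)
    img, _ = _base_scene(spec, rng)
    return img, np.roll(img, (dy, dx), axis=(0, 1))
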