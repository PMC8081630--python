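"""Objective fusion-quality measures: SD, entropy, mutual information, Q^AB/F.

All four operate on 8-bit intensity scales.  Float images in [0, 1] are
quantised to 256 levels first; integer-range inputs are used as-is.

* ``std_dev`` — population standard deviation of intensities (contrast).
* ``entropy`` — Shannon entropy of the 256-bin histogram, in bits.
* ``mutual_information_fusion`` — I(A;F) + I(B;F) from 256x256 joint
  histograms: how much source information the fused image carries.
* ``q_abf`` — the Xydeas–Petrović edge-transfer measure: per-pixel Sobel
  edge strength and orientation preservation, pushed through sigmoids and
  weighted by source edge strength.  The default sigmoids are normalised so
  that perfect preservation scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import sobel

from .errors import InputError

__all__ = [
    "QabfConstants",
    "QualityReport",
    "std_dev",
    "entropy",
    "mutual_information_fusion",
    "q_abf",
    "quality_report",
]


@dataclass(frozen=True)
class QabfConstants:
    """Sigmoid constants of the edge-preservation measure.

    ``normalized=True`` rescales each sigmoid by its value at perfect
    preservation (G = 1, A = 1) so the measure's upper limit is exactly 1;
    with ``normalized=False`` the raw Γ amplitudes are used instead and the
    attainable maximum is ≈ 0.975.
    """

    gamma_g: float = 0.9994
    kappa_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    kappa_a: float = -22.0
    sigma_a: float = 0.8
    normalized: bool = True


@dataclass
class QualityReport:
    sd: float
    en: float
    mi: float
    q_abf: float

    def as_dict(self) -> dict:
        return asdict(self)


def _as_levels(img: np.ndarray) -> np.ndarray:
    """Quantise to integer levels 0..255."""
    img = np.asarray(img)
    if img.size == 0:
        raise InputError("empty image")
    if not np.all(np.isfinite(img)):
        raise InputError("image contains non-finite values")
    img = np.asarray(img, dtype=np.float64)
    if img.max() <= 1.0 and img.min() >= 0.0:
        img = img * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.int64)


def std_dev(img: np.ndarray) -> float:
    """Population standard deviation on the 8-bit intensity scale."""
    return float(_as_levels(img).std())


def entropy(img: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy of the intensity histogram, in bits (0·log 0 := 0)."""
    levels = _as_levels(img)
    hist = np.bincount(levels.ravel(), minlength=n_bins).astype(np.float64)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mi(x: np.ndarray, y: np.ndarray) -> float:
    joint = np.bincount(x.ravel() * 256 + y.ravel(), minlength=256 * 256).astype(np.float64)
    joint = joint.reshape(256, 256) / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mutual_information_fusion(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Fusion MI = I(A;F) + I(B;F), in bits, from 256x256 joint histograms."""
    a, b, f = _as_levels(a), _as_levels(b), _as_levels(f)
    if not (a.shape == b.shape == f.shape):
        raise InputError("images must share one shape")
    return _mi(a, f) + _mi(b, f)


def _edges(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(img, dtype=np.float64)
    gx = sobel(img, axis=1, mode="wrap")
    gy = sobel(img, axis=0, mode="wrap")
    g = np.hypot(gx, gy)
    alpha = np.arctan2(gy, np.where((gx == 0) & (gy == 0), 1.0, gx))
    # fold gradient direction to edge orientation in (-pi/2, pi/2]
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _sigmoid(x: np.ndarray, gamma: float, kappa: float, sigma: float) -> np.ndarray:
    return gamma / (1.0 + np.exp(kappa * (x - sigma)))


def _preservation(
    g_s: np.ndarray, a_s: np.ndarray, g_f: np.ndarray, a_f: np.ndarray, c: QabfConstants
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_s > g_f, g_f / g_s, np.where(g_f > 0, g_s / g_f, 0.0))
    ratio = np.where((g_s == 0) & (g_f == 0), 1.0, ratio)
    delta = np.abs(a_s - a_f)
    delta = np.minimum(delta, np.pi - delta)  # orientations are mod pi
    align = 1.0 - delta / (np.pi / 2.0)
    q_g = _sigmoid(ratio, c.gamma_g, c.kappa_g, c.sigma_g)
    q_a = _sigmoid(align, c.gamma_a, c.kappa_a, c.sigma_a)
    if c.normalized:
        q_g = q_g / _sigmoid(np.float64(1.0), c.gamma_g, c.kappa_g, c.sigma_g)
        q_a = q_a / _sigmoid(np.float64(1.0), c.gamma_a, c.kappa_a, c.sigma_a)
    return q_g * q_a


def q_abf(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, constants: QabfConstants | None = None
) -> float:
    """Edge-information transfer from both sources into the fused image.

    Per pixel, the edge-strength ratio and orientation agreement between a
    source and the fused image are mapped through sigmoids and multiplied;
    the two source preservation maps are then averaged with the sources'
    own edge strengths as weights.  Returns a value in [0, 1].
    """
    c = constants or QabfConstants()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if not (a.shape == b.shape == f.shape):
        raise InputError("images must share one shape")
    g_a, al_a = _edges(a)
    g_b, al_b = _edges(b)
    g_f, al_f = _edges(f)
    q_af = _preservation(g_a, al_a, g_f, al_f, c)
    q_bf = _preservation(g_b, al_b, g_f, al_f, c)
    w_a, w_b = g_a, g_b
    denom = (w_a + w_b).sum()
    if denom == 0:
        warnings.warn("both sources have zero gradient everywhere; Q^AB/F := 0")
        return 0.0
    return float(np.clip((q_af * w_a + q_bf * w_b).sum() / denom, 0.0, 1.0))


def quality_report(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> QualityReport:
    """All four measures of a fused image against its two sources."""
    return QualityReport(
        sd=std_dev(f),
        en=entropy(f),
        mi=mutual_information_fusion(a, b, f),
        q_abf=q_abf(a, b, f),
    )
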