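"""End-to-end fusion orchestration, image I/O and color handling.

``fuse_pair`` runs the whole chain on two co-registered grayscale images:
shearlet decomposition of both, the CNN-scored rule on each level's
high-pass planes, the SIFT-matching rule on the low-pass planes, inverse
transform, clamp.  ``fuse_color_pair`` fuses an anatomical grayscale image
with a functional color image by fusing luma and carrying the color
source's chroma, the standard recipe for anatomical–functional overlays.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from . import sist
from .cnn_model import ScoringModel, load_model
from .errors import ConfigurationError, FormatError, InputError
from .highpass_rule import GuidedFilterParams, fuse_highpass_level
from .lowpass_rule import (
    DEFAULT_COLOCATION_TOL,
    DEFAULT_SUPPORT_RADIUS_MULT,
    fuse_lowpass_pair,
)
from .metrics import QualityReport, quality_report

__all__ = [
    "FusionConfig",
    "FusionResult",
    "fuse_pair",
    "fuse_color_pair",
    "read_image",
    "write_image",
    "average_baseline",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
]

log = logging.getLogger("sistfuse")


@dataclass(frozen=True)
class FusionConfig:
    sist: sist.SISTConfig = field(default_factory=sist.SISTConfig)
    cnn_checkpoint: str | Path | None = None
    tau: float = 0.5
    guided: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    stride: int = 2
    match_mode: str = "ratio"
    colocation_tol: float = DEFAULT_COLOCATION_TOL
    support_radius_mult: float = DEFAULT_SUPPORT_RADIUS_MULT
    lowpass_fallback: str = "second"
    color_mode: str = "luma"
    seed: int = 0


@dataclass
class FusionResult:
    fused: np.ndarray
    decision_maps: list[np.ndarray]
    match_map: np.ndarray
    quality: QualityReport
    provenance: dict


# ---------------------------------------------------------------- I/O

_SUPPORTED_MODES = {"L": 255.0, "I;16": 65535.0, "RGB": 255.0}


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF as float in [0, 1]; 2-D grayscale or HxWx3 RGB."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode not in _SUPPORTED_MODES:
                raise FormatError(f"{path}: unsupported image mode {im.mode!r}")
            scale = _SUPPORTED_MODES[im.mode]
            arr = np.asarray(im, dtype=np.float64) / scale
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"{path}: unreadable image ({exc})") from exc
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write float [0, 1] data as an 8-bit PNG/TIFF (grayscale or RGB)."""
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise InputError("refusing to write non-finite pixel values")
    u8 = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(u8).save(Path(path))


# ---------------------------------------------------------------- color

# full-range BT.601 luma/chroma, exactly invertible in float
_RGB2YCC = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)
_YCC2RGB = np.linalg.inv(_RGB2YCC)


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    ycc = rgb @ _RGB2YCC.T
    ycc[..., 1:] += 0.5
    return ycc


def ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    ycc = ycc.copy()
    ycc[..., 1:] -= 0.5
    return ycc @ _YCC2RGB.T


# ---------------------------------------------------------------- fusion

def _resolve_model(config: FusionConfig, model: ScoringModel | None) -> ScoringModel:
    if model is not None:
        return model
    if config.cnn_checkpoint is None:
        raise ConfigurationError("no scoring model: pass model= or set cnn_checkpoint")
    path = Path(config.cnn_checkpoint)
    if not path.exists():
        raise ConfigurationError(f"checkpoint not found: {path}")
    return load_model(path)


def _provenance(config: FusionConfig, model: ScoringModel) -> dict:
    digest = hashlib.sha256()
    for k in sorted(model.params):
        digest.update(model.params[k].tobytes())
    return {
        "config": repr(config),
        "model_hash": digest.hexdigest()[:16],
        "model_metadata": dict(model.metadata),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def fuse_pair(
    image_a: np.ndarray,
    image_b: np.ndarray,
    config: FusionConfig | None = None,
    model: ScoringModel | None = None,
) -> FusionResult:
    """Fuse two co-registered grayscale images in the shearlet domain."""
    config = config or FusionConfig()
    image_a = np.asarray(image_a, dtype=np.float64)
    image_b = np.asarray(image_b, dtype=np.float64)
    if image_a.shape != image_b.shape:
        raise InputError(f"image shapes differ: {image_a.shape} vs {image_b.shape}")
    if image_a.ndim != 2:
        raise InputError("fuse_pair expects 2-D grayscale images")
    model = _resolve_model(config, model)

    t0 = time.perf_counter()
    padded_a, orig_shape = sist.pad_to_pow2(image_a)
    padded_b, _ = sist.pad_to_pow2(image_b)
    pyr_a = sist.sist_decompose(padded_a, config.sist)
    pyr_b = sist.sist_decompose(padded_b, config.sist)
    log.debug("decomposition: %.2fs", time.perf_counter() - t0)

    fused_levels: list[list[np.ndarray]] = []
    decision_maps: list[np.ndarray] = []
    for planes_a, planes_b in zip(pyr_a.highpass, pyr_b.highpass):
        fused, d = fuse_highpass_level(
            model,
            planes_a,
            planes_b,
            stride=config.stride,
            tau=config.tau,
            params=config.guided,
        )
        fused_levels.append(fused)
        decision_maps.append(d)
    log.debug("high-pass rule: %.2fs", time.perf_counter() - t0)

    fused_low, match_map = fuse_lowpass_pair(
        pyr_a.lowpass,
        pyr_b.lowpass,
        mode=config.match_mode,
        tol_px=config.colocation_tol,
        support_radius_mult=config.support_radius_mult,
        fallback=config.lowpass_fallback,
    )
    log.debug("low-pass rule: %.2fs", time.perf_counter() - t0)

    fused_pyr = sist.ShearletPyramid(lowpass=fused_low, highpass=fused_levels)
    fused = sist.sist_reconstruct(fused_pyr, config.sist)
    fused = np.clip(fused, 0.0, 1.0)[: orig_shape[0], : orig_shape[1]]

    h, w = orig_shape
    return FusionResult(
        fused=fused,
        decision_maps=[d[:h, :w] for d in decision_maps],
        match_map=match_map[:h, :w],
        quality=quality_report(image_a, image_b, fused),
        provenance=_provenance(config, model),
    )


def fuse_color_pair(
    gray_anatomical: np.ndarray,
    color_functional: np.ndarray,
    config: FusionConfig | None = None,
    model: ScoringModel | None = None,
) -> FusionResult:
    """Fuse a grayscale image with an RGB image via luma fusion.

    The color image's luma is fused with the grayscale source; its chroma
    channels pass through untouched, preserving the functional color coding.
    """
    config = config or FusionConfig()
    gray = np.asarray(gray_anatomical, dtype=np.float64)
    color = np.asarray(color_functional, dtype=np.float64)
    if color.ndim != 3 or color.shape[-1] != 3:
        raise InputError("color_functional must be an HxWx3 RGB image")
    if gray.shape != color.shape[:2]:
        raise InputError("image shapes differ")
    ycc = rgb_to_ycbcr(color)
    result = fuse_pair(gray, ycc[..., 0], config=config, model=model)
    out = ycc.copy()
    out[..., 0] = result.fused
    fused_rgb = np.clip(ycbcr_to_rgb(out), 0.0, 1.0)
    result.fused = fused_rgb
    return result


def average_baseline(image_a: np.ndarray, image_b: np.ndarray) -> np.ndarray:
    """Naive per-pixel average, the comparison baseline."""
    return 0.5 * (np.asarray(image_a, dtype=np.float64) + np.asarray(image_b, dtype=np.float64))
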