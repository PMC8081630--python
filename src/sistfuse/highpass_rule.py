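"""High-pass fusion rule: CNN feature detection, segmentation, verification.

The chain runs per decomposition level:

1. slide the siamese scorer over the pair of aggregate high-pass planes to
   get a score map (one score per 16x16 window),
2. spread window scores back to pixels, averaging overlaps → feature map M,
3. threshold M at tau (strict ``>``) → binary map T,
4. refine T with a guided filter steered by the mean source plane → soft
   decision map D in [0, 1] (consistency verification),
5. combine the subbands per pixel: ``F = D*A + (1-D)*B``.

One decision map is computed per level from the root-sum-square energy over
that level's directions and applied to every direction of the level; this
keeps the orientation bands of a level mutually consistent and costs a
single CNN sweep instead of one per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cnn_model import ScoringModel, score_batch
from .errors import ConfigurationError, InputError, StructureError

__all__ = [
    "ScoreMap",
    "GuidedFilterParams",
    "compute_score_map",
    "score_to_feature_map",
    "binarize",
    "guided_filter",
    "refine_decision",
    "fuse_highpass",
    "fuse_highpass_level",
]


@dataclass(frozen=True)
class GuidedFilterParams:
    """Guided-filter window radius (pixels) and ridge regularisation."""

    radius: int = 8
    eps: float = 0.1

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ConfigurationError("radius must be >= 1")
        if self.eps <= 0:
            raise ConfigurationError("eps must be > 0")


@dataclass
class ScoreMap:
    """Per-window CNN scores over a sliding-window grid."""

    values: np.ndarray  # (ny, nx), each in [0, 1]
    stride: int
    patch_size: int


def _window_starts(extent: int, patch: int, stride: int) -> np.ndarray:
    return np.arange(0, extent - patch + 1, stride)


def compute_score_map(
    model: ScoringModel, a_h: np.ndarray, b_h: np.ndarray, stride: int = 2
) -> ScoreMap:
    """Slide the scorer over the plane pair; one score per window position.

    Each window pair is jointly rescaled before scoring: both patches are
    divided by their shared maximum absolute value and re-centred on 0.5,
    mapping the pair into [0, 1] around mid-gray.  Subband coefficients are
    signed and unbounded, while the network was trained on [0, 1] intensity
    patches whose blurred members are smooth and mid-gray — this mapping
    sends a detail-free window to a flat 0.5 patch, exactly the degraded
    appearance the scorer knows.  Windows with no joint contrast are fed as
    equal patches and hence score exactly 0.5.
    """
    a_h = np.asarray(a_h, dtype=np.float64)
    b_h = np.asarray(b_h, dtype=np.float64)
    if a_h.shape != b_h.shape:
        raise InputError(f"plane shapes differ: {a_h.shape} vs {b_h.shape}")
    p = model.config.patch_size
    h, w = a_h.shape
    if h < p or w < p:
        raise InputError(f"plane {a_h.shape} smaller than patch size {p}")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")

    wa = np.lib.stride_tricks.sliding_window_view(a_h, (p, p))[::stride, ::stride]
    wb = np.lib.stride_tricks.sliding_window_view(b_h, (p, p))[::stride, ::stride]
    ny, nx = wa.shape[:2]
    wa = wa.reshape(-1, p, p)
    wb = wb.reshape(-1, p, p)
    scale = np.maximum(
        np.abs(wa).max(axis=(1, 2)), np.abs(wb).max(axis=(1, 2))
    )[:, None, None]
    flat = scale[:, 0, 0] < 1e-12
    scale[flat] = 1.0
    na = 0.5 + 0.5 * wa / scale
    nb = 0.5 + 0.5 * wb / scale
    scores = score_batch(model, na, nb).reshape(ny, nx)
    return ScoreMap(values=scores, stride=stride, patch_size=p)


def score_to_feature_map(score_map: ScoreMap, shape: tuple[int, int]) -> np.ndarray:
    """Spread window scores to pixels, averaging overlapping windows.

    Pixels left uncovered by the window grid (possible at the far border
    when the stride does not divide the extent) inherit the nearest covered
    value.
    """
    h, w = shape
    p, s = score_map.patch_size, score_map.stride
    ys = _window_starts(h, p, s)
    xs = _window_starts(w, p, s)
    if score_map.values.shape != (len(ys), len(xs)):
        raise StructureError(
            f"score grid {score_map.values.shape} inconsistent with shape {shape}, "
            f"patch {p}, stride {s}"
        )
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            acc[y : y + p, x : x + p] += score_map.values[i, j]
            cnt[y : y + p, x : x + p] += 1.0
    covered = cnt > 0
    m = np.zeros(shape)
    m[covered] = acc[covered] / cnt[covered]
    if not covered.all():
        _, (iy, ix) = ndimage.distance_transform_edt(~covered, return_indices=True)
        m = m[iy, ix]
    return m


def binarize(m: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Strict threshold: 1 where M > tau, else 0."""
    if not 0.0 < tau < 1.0:
        raise ConfigurationError(f"tau must be in (0, 1), got {tau}")
    return (np.asarray(m) > tau).astype(np.float64)


def _box_mean(x: np.ndarray, r: int) -> np.ndarray:
    """Mean over (2r+1)^2 windows clipped at the image border (integral image)."""
    ones = np.ones_like(x)
    return _box_sum(x, r) / _box_sum(ones, r)


def _box_sum(x: np.ndarray, r: int) -> np.ndarray:
    out = x
    for axis in (0, 1):
        c = np.cumsum(out, axis=axis)
        n = out.shape[axis]
        c = np.concatenate([np.zeros_like(np.take(c, [0], axis=axis)), c], axis=axis)
        hi = np.minimum(np.arange(n) + r + 1, n)
        lo = np.maximum(np.arange(n) - r, 0)
        out = np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)
    return out


def guided_filter(
    guide: np.ndarray, input_map: np.ndarray, params: GuidedFilterParams | None = None
) -> np.ndarray:
    """Edge-preserving guided filter (local linear model with ridge eps).

    In each (2r+1)^2 window the input is regressed on the guide,
    ``a = cov(I, p) / (var(I) + eps)``, ``b = mean(p) - a * mean(I)``; the
    coefficients are then averaged over all windows covering a pixel and the
    output is ``q = mean(a) * I + mean(b)``.  Windows are clipped at the
    border (no padding), so border statistics use only real pixels.
    """
    params = params or GuidedFilterParams()
    guide = np.asarray(guide, dtype=np.float64)
    p = np.asarray(input_map, dtype=np.float64)
    if guide.shape != p.shape:
        raise InputError(f"guide shape {guide.shape} != input shape {p.shape}")
    r, eps = params.radius, params.eps
    mean_i = _box_mean(guide, r)
    mean_p = _box_mean(p, r)
    corr_ip = _box_mean(guide * p, r)
    corr_ii = _box_mean(guide * guide, r)
    cov_ip = corr_ip - mean_i * mean_p
    var_i = corr_ii - mean_i * mean_i
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    return _box_mean(a, r) * guide + _box_mean(b, r)


def refine_decision(
    t: np.ndarray, guide: np.ndarray, params: GuidedFilterParams | None = None
) -> np.ndarray:
    """Consistency verification: guided-filter the binary map, clamp to [0, 1].

    The result is kept soft (real-valued): the pixel-weighted fusion below
    uses it directly as a convex weight rather than re-binarising.
    """
    return np.clip(guided_filter(guide, t, params), 0.0, 1.0)


def fuse_highpass(a_h: np.ndarray, b_h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Pixel-weighted combination ``F = D*A + (1-D)*B``."""
    a_h = np.asarray(a_h)
    b_h = np.asarray(b_h)
    d = np.asarray(d)
    if not (a_h.shape == b_h.shape == d.shape):
        raise InputError(
            f"shape mismatch: {a_h.shape}, {b_h.shape}, decision {d.shape}"
        )
    return d * a_h + (1.0 - d) * b_h


def fuse_highpass_level(
    model: ScoringModel,
    planes_a: list[np.ndarray],
    planes_b: list[np.ndarray],
    stride: int = 2,
    tau: float = 0.5,
    params: GuidedFilterParams | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Fuse one level's directional planes under a shared decision map.

    The scorer sees the level's aggregate detail planes — the signed sum of
    that level's directional planes, i.e. the level's band-pass residual —
    centred patch-wise on mid-gray (see ``compute_score_map``).  One shared
    map keeps the orientation bands of a level mutually consistent and costs
    a single CNN sweep instead of one per direction.  The guided filter is
    steered by the mean absolute detail of the two sources, so the decision
    boundary relaxes along real structure.  Returns the fused planes and the
    decision map.
    """
    if len(planes_a) != len(planes_b):
        raise InputError("levels have different direction counts")
    agg_a = sum(planes_a)
    agg_b = sum(planes_b)
    smap = compute_score_map(model, agg_a, agg_b, stride=stride)
    m = score_to_feature_map(smap, agg_a.shape)
    t = binarize(m, tau)
    guide = 0.5 * (np.abs(agg_a) + np.abs(agg_b))
    d = refine_decision(t, guide, params)
    fused = [fuse_highpass(pa, pb, d) for pa, pb in zip(planes_a, planes_b)]
    return fused, d
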