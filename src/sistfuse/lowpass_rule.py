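"""Low-pass fusion rule driven by SIFT descriptor matching.

Keypoints and 128-dim descriptors are extracted from both low-pass
subbands.  Descriptors are matched by Euclidean distance — either with the
standard Lowe ratio test ("ratio", the default) or with the literal
second-largest-distance criterion ("paper") — and surviving matches are kept
only where the two keypoints are colocated (the images are co-registered,
so matched content should sit at the same place).  Each surviving match
stamps a binary disk into a dense match map, which then selects the first
source inside matched regions and the second elsewhere:

    F_L = match_map * A_L + (1 - match_map) * B_L
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT

from .errors import InputError

__all__ = [
    "Keypoint",
    "SIFTDescriptor",
    "MatchRecord",
    "detect_sift",
    "match_descriptors",
    "filter_colocated",
    "build_match_map",
    "fuse_lowpass",
    "fuse_lowpass_pair",
]

#: the descriptor is built from a ~6 sigma neighbourhood of its keypoint
DEFAULT_SUPPORT_RADIUS_MULT = 6.0
DEFAULT_COLOCATION_TOL = 2.0
LOWE_RATIO = 0.75


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    scale: float  # gaussian sigma of the detection scale
    orientation: float  # radians


@dataclass(frozen=True)
class SIFTDescriptor:
    keypoint: Keypoint
    vector: np.ndarray  # 128 nonnegative reals, unit L2 norm


@dataclass
class MatchRecord:
    i: int  # index into the first descriptor set
    j: int  # index into the second descriptor set
    distance: float
    colocated: bool = False


def detect_sift(lowpass: np.ndarray) -> list[SIFTDescriptor]:
    """SIFT keypoints + unit-normalised descriptors of one low-pass plane.

    Returns an empty list (not an error) when the plane has no detectable
    structure, e.g. a constant plane.
    """
    plane = np.asarray(lowpass, dtype=np.float64)
    if plane.ndim != 2:
        raise InputError("expected a 2-D plane")
    detector = SIFT()
    try:
        detector.detect_and_extract(plane)
    except RuntimeError:  # no features found
        return []
    descriptors = []
    vecs = detector.descriptors.astype(np.float64)
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vecs /= norms
    for (row, col), sigma, ori, vec in zip(
        detector.keypoints, detector.sigmas, detector.orientations, vecs
    ):
        kp = Keypoint(x=float(col), y=float(row), scale=float(sigma), orientation=float(ori))
        descriptors.append(SIFTDescriptor(keypoint=kp, vector=vec))
    return descriptors


def match_descriptors(
    set1: list[SIFTDescriptor],
    set2: list[SIFTDescriptor],
    mode: str = "ratio",
) -> list[MatchRecord]:
    """Match each query descriptor in set1 to its nearest neighbour in set2.

    mode "ratio": accept when nearest < 0.75 x second-nearest (Lowe).
    mode "paper": accept when the nearest distance is strictly below the
    second entry of the sorted distance list, i.e. strictly below every
    other candidate's distance — an unthresholded uniqueness criterion that
    accepts almost every query with a strict nearest neighbour.

    Queries with fewer than two candidates produce no match (both criteria
    need a second distance).
    """
    if mode not in ("ratio", "paper"):
        raise InputError(f"unknown matching mode {mode!r}")
    if not set1 or len(set2) < 2:
        return []
    d1 = np.stack([d.vector for d in set1])
    d2 = np.stack([d.vector for d in set2])
    # all pairwise Euclidean distances between unit vectors
    cross = np.clip(2.0 - 2.0 * (d1 @ d2.T), 0.0, None)
    dist = np.sqrt(cross)
    matches = []
    for i in range(len(set1)):
        row = dist[i]
        j = int(row.argmin())
        nearest = row[j]
        second_nearest = np.partition(row, 1)[1]
        if mode == "ratio":
            ok = nearest < LOWE_RATIO * second_nearest
        else:
            ok = nearest < second_nearest
        if ok:
            matches.append(MatchRecord(i=i, j=j, distance=float(nearest)))
    return matches


def filter_colocated(
    matches: list[MatchRecord],
    set1: list[SIFTDescriptor],
    set2: list[SIFTDescriptor],
    tol_px: float = DEFAULT_COLOCATION_TOL,
) -> list[MatchRecord]:
    """Keep matches whose keypoints sit within tol_px of each other (inclusive)."""
    if tol_px < 0:
        raise InputError("tol_px must be >= 0")
    kept = []
    for m in matches:
        k1 = set1[m.i].keypoint
        k2 = set2[m.j].keypoint
        if np.hypot(k1.x - k2.x, k1.y - k2.y) <= tol_px:
            kept.append(MatchRecord(i=m.i, j=m.j, distance=m.distance, colocated=True))
    return kept


def build_match_map(
    matches: list[MatchRecord],
    set1: list[SIFTDescriptor],
    shape: tuple[int, int],
    support_radius_mult: float = DEFAULT_SUPPORT_RADIUS_MULT,
) -> np.ndarray:
    """Dense binary map: union of disks around surviving matches' keypoints.

    The disk radius is ``support_radius_mult`` times the keypoint's scale,
    approximating the descriptor's support region.
    """
    h, w = shape
    out = np.zeros(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    for m in matches:
        kp = set1[m.i].keypoint
        radius = support_radius_mult * kp.scale
        out[(xx - kp.x) ** 2 + (yy - kp.y) ** 2 <= radius**2] = 1.0
    return out


def fuse_lowpass(a_l: np.ndarray, b_l: np.ndarray, match_map: np.ndarray) -> np.ndarray:
    """Select A inside matched regions, B elsewhere: ``F = m*A + (1-m)*B``."""
    a_l = np.asarray(a_l)
    b_l = np.asarray(b_l)
    match_map = np.asarray(match_map)
    if not (a_l.shape == b_l.shape == match_map.shape):
        raise InputError(
            f"shape mismatch: {a_l.shape}, {b_l.shape}, map {match_map.shape}"
        )
    return match_map * a_l + (1.0 - match_map) * b_l


def _normalize_for_detection(plane: np.ndarray) -> np.ndarray:
    lo, hi = plane.min(), plane.max()
    if hi - lo < 1e-12:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def fuse_lowpass_pair(
    a_l: np.ndarray,
    b_l: np.ndarray,
    mode: str = "ratio",
    tol_px: float = DEFAULT_COLOCATION_TOL,
    support_radius_mult: float = DEFAULT_SUPPORT_RADIUS_MULT,
    fallback: str = "second",
) -> tuple[np.ndarray, np.ndarray]:
    """Full low-pass rule: detect, match, colocate, rasterise, combine.

    When either plane yields too few descriptors for matching, the match map
    is all-zero, so the result is the second source ("second" fallback) or,
    with ``fallback='mean'``, the per-pixel average.  Returns (fused plane,
    match map).
    """
    set1 = detect_sift(_normalize_for_detection(np.asarray(a_l, dtype=np.float64)))
    set2 = detect_sift(_normalize_for_detection(np.asarray(b_l, dtype=np.float64)))
    matches = match_descriptors(set1, set2, mode=mode)
    colocated = filter_colocated(matches, set1, set2, tol_px=tol_px)
    match_map = build_match_map(colocated, set1, np.asarray(a_l).shape, support_radius_mult)
    if not colocated and (not set1 or len(set2) < 2):
        warnings.warn(
            "low-pass rule found too few SIFT descriptors to match; "
            f"falling back to {fallback!r}",
            stacklevel=2,
        )
        if fallback == "mean":
            return 0.5 * (np.asarray(a_l) + np.asarray(b_l)), match_map
    return fuse_lowpass(a_l, b_l, match_map), match_map
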