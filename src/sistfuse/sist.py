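"""Shift-invariant shearlet transform (SIST).

The transform separates an image into scales with a non-subsampled (à-trous)
pyramid and splits each scale's high-pass residual into orientation bands with
Meyer-windowed shearing filters applied in the FFT domain.  Nothing is ever
downsampled, so every coefficient plane keeps the input resolution and the
whole transform commutes with circular shifts.

Two structural identities make the transform trivially invertible:

* pyramid:  ``g_j = f_{j-1} - f_j``  so  ``f_0 = f_M + sum_j g_j``;
* shearing: the squared directional windows tile unity at every frequency,
  and each directional plane is ``ifft2(fft2(g_j) * U_k**2)``, so the planes
  of one level sum back to ``g_j`` exactly.

All filtering is circular (periodic), matching the FFT-domain definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError, StructureError

__all__ = [
    "SISTConfig",
    "ShearletPyramid",
    "build_shearing_filters",
    "nsp_decompose",
    "sist_decompose",
    "sist_reconstruct",
    "save_pyramid",
    "load_pyramid",
    "pad_to_pow2",
]

#: Maximally-flat (binomial) half-band low-pass kernel used by the pyramid.
_MAXFLAT_KERNELS = {
    "maxflat": np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0,
}

_MIN_SIZE = 32


@dataclass(frozen=True)
class SISTConfig:
    """Decomposition settings.

    levels
        Number of pyramid scales M.  Level 1 is the finest scale.
    directions_per_level
        Orientation-band count for each level, finest first.  Each entry must
        be a power of two; finer scales conventionally get more directions.
    pyramid_filter_name
        Name of the non-subsampled pyramid low-pass kernel.
    """

    levels: int = 4
    directions_per_level: tuple[int, ...] = (32, 32, 16, 16)
    pyramid_filter_name: str = "maxflat"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        dirs = tuple(int(d) for d in self.directions_per_level)
        object.__setattr__(self, "directions_per_level", dirs)
        if len(dirs) != self.levels:
            raise ConfigurationError(
                f"directions_per_level has {len(dirs)} entries for {self.levels} levels"
            )
        for d in dirs:
            if d < 2 or d & (d - 1):
                raise ConfigurationError(f"direction count {d} is not a power of two >= 2")
        if self.pyramid_filter_name not in _MAXFLAT_KERNELS:
            raise ConfigurationError(f"unknown pyramid filter {self.pyramid_filter_name!r}")


@dataclass
class ShearletPyramid:
    """One low-pass plane plus per-level lists of directional high-pass planes."""

    lowpass: np.ndarray
    highpass: list[list[np.ndarray]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lowpass.shape

    def validate(self, config: SISTConfig) -> None:
        if len(self.highpass) != config.levels:
            raise StructureError(
                f"pyramid has {len(self.highpass)} levels, config expects {config.levels}"
            )
        for j, (planes, n_dir) in enumerate(
            zip(self.highpass, config.directions_per_level), start=1
        ):
            if len(planes) != n_dir:
                raise StructureError(
                    f"level {j} has {len(planes)} directional planes, expected {n_dir}"
                )
            for p in planes:
                if p.shape != self.lowpass.shape:
                    raise StructureError("directional plane shape differs from low-pass plane")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InputError(f"expected a 2-D image, got ndim={image.ndim}")
    if image.size == 0:
        raise InputError("empty image")
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite values")
    return image


def _meyer_nu(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: smooth 0→1 ramp with nu(x) + nu(1-x) = 1."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _pseudo_polar_angle(h: int, w: int) -> np.ndarray:
    """Pseudo-polar angular coordinate u on the (folded) FFT grid.

    Frequencies are folded through the origin (u(-xi) = u(xi)), then the
    direction is parametrised by slope rather than true angle:

        |theta| <= pi/4          u = fy/fx          in [-1, 1]
        theta in (pi/4, pi/2]    u = 2 - fx/fy      in (1, 2]
        theta in (-pi/2, -pi/4)  u = -2 - fx/fy     in (-2, -1)

    u lives on a circle of circumference 4 (u = -2 and u = 2 coincide).
    The DC bin gets u = nan and is handled separately.
    """
    fy = np.fft.fftfreq(h)[:, None] * np.ones((1, w))
    fx = np.ones((h, 1)) * np.fft.fftfreq(w)[None, :]
    # fold so the representative has fx > 0, or fx == 0 and fy > 0
    neg = (fx < 0) | ((fx == 0) & (fy < 0))
    fx = np.where(neg, -fx, fx)
    fy = np.where(neg, -fy, fy)

    u = np.full((h, w), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        cone_h = (fx >= np.abs(fy)) & (fx > 0)
        u = np.where(cone_h, fy / np.where(fx == 0, 1, fx), u)
        cone_v = np.abs(fy) > fx
        ratio = np.where(cone_v, fx / np.where(fy == 0, 1, fy), 0.0)
        u = np.where(cone_v & (fy > 0), 2.0 - ratio, u)
        u = np.where(cone_v & (fy < 0), -2.0 - ratio, u)
    return u


def build_shearing_filters(size: tuple[int, int], n_directions: int) -> list[np.ndarray]:
    """Frequency-domain directional windows on the pseudo-polar grid.

    Returns ``n_directions`` real nonnegative windows (unshifted FFT layout)
    built from a Meyer window in the pseudo-polar angle and mapped to the
    Cartesian FFT grid.  Their squared magnitudes sum to 1 at every frequency
    bin, which is what makes the directional split invertible by summation.
    """
    h, w = size
    if n_directions < 2 or n_directions & (n_directions - 1):
        raise ConfigurationError(
            f"n_directions must be a power of two >= 2, got {n_directions}"
        )
    if min(h, w) < _MIN_SIZE:
        raise ConfigurationError(f"image size {size} too small (min {_MIN_SIZE})")
    if n_directions > min(h, w):
        raise ConfigurationError(
            f"{n_directions} directions cannot be resolved on a {h}x{w} grid"
        )

    u = _pseudo_polar_angle(h, w)
    dc = np.isnan(u)
    spacing = 4.0 / n_directions
    windows = []
    for k in range(n_directions):
        center = k * spacing  # center 0 lies on the horizontal-frequency axis
        d = np.abs((u - center + 2.0) % 4.0 - 2.0)  # circular distance in u
        win = np.where(d < spacing, np.cos(0.5 * np.pi * _meyer_nu(d / spacing)), 0.0)
        # every window carries an equal share of the DC bin
        win[dc] = 1.0 / np.sqrt(n_directions)
        windows.append(win)
    return windows


def _atrous_lowpass(image: np.ndarray, kernel: np.ndarray, level: int) -> np.ndarray:
    """One à-trous low-pass step: kernel dilated by 2**(level-1), circular."""
    dilation = 2 ** (level - 1)
    k = np.zeros((len(kernel) - 1) * dilation + 1)
    k[::dilation] = kernel
    out = ndimage.correlate1d(image, k, axis=0, mode="wrap")
    return ndimage.correlate1d(out, k, axis=1, mode="wrap")


def nsp_decompose(
    image: np.ndarray, levels: int, filter_name: str = "maxflat"
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Non-subsampled pyramid: low-pass f_M plus high-pass residuals g_1..g_M.

    The high-pass at each level is the difference of successive low-pass
    images, so ``f_M + sum(g_j) == image`` to machine precision.
    """
    image = _check_image(image)
    if levels < 1:
        raise ConfigurationError("levels must be >= 1")
    if filter_name not in _MAXFLAT_KERNELS:
        raise ConfigurationError(f"unknown pyramid filter {filter_name!r}")
    kernel = _MAXFLAT_KERNELS[filter_name]

    f = image
    highpass = []
    for j in range(1, levels + 1):
        f_next = _atrous_lowpass(f, kernel, j)
        highpass.append(f - f_next)
        f = f_next
    return f, highpass


_filter_cache: dict[tuple[int, int, int], list[np.ndarray]] = {}


def _squared_windows(size: tuple[int, int], n_directions: int) -> list[np.ndarray]:
    key = (size[0], size[1], n_directions)
    if key not in _filter_cache:
        _filter_cache[key] = [w**2 for w in build_shearing_filters(size, n_directions)]
    return _filter_cache[key]


def sist_decompose(image: np.ndarray, config: SISTConfig | None = None) -> ShearletPyramid:
    """Forward transform: pyramid split, then FFT-domain directional split.

    Each directional plane is the (real) inverse FFT of the level residual's
    FFT multiplied by the squared shearing window; folding analysis and
    synthesis windows into one application keeps reconstruction a plain sum.
    """
    config = config or SISTConfig()
    image = _check_image(image)
    lowpass, residuals = nsp_decompose(image, config.levels, config.pyramid_filter_name)

    highpass: list[list[np.ndarray]] = []
    for g, n_dir in zip(residuals, config.directions_per_level):
        spectrum = np.fft.fft2(g)
        planes = []
        for win2 in _squared_windows(image.shape, n_dir):
            plane = np.fft.ifft2(spectrum * win2)
            planes.append(plane.real)  # windows are origin-symmetric: imag ~ 0
        highpass.append(planes)
    return ShearletPyramid(lowpass=lowpass, highpass=highpass)


def sist_reconstruct(pyramid: ShearletPyramid, config: SISTConfig | None = None) -> np.ndarray:
    """Inverse transform: sum the directional planes per level, then the levels."""
    config = config or SISTConfig()
    pyramid.validate(config)
    out = pyramid.lowpass.copy()
    for planes in pyramid.highpass:
        for p in planes:
            out += p
    return out


def save_pyramid(pyramid: ShearletPyramid, path) -> None:
    """Serialize to a single ``.npz`` archive (plane names: low, hp_L{j}_D{k})."""
    arrays = {"low": pyramid.lowpass}
    for j, planes in enumerate(pyramid.highpass, start=1):
        for k, p in enumerate(planes):
            arrays[f"hp_L{j}_D{k}"] = p
    np.savez(path, **arrays)


def load_pyramid(path) -> ShearletPyramid:
    with np.load(path) as data:
        lowpass = data["low"]
        levels: dict[int, dict[int, np.ndarray]] = {}
        for name in data.files:
            if name == "low":
                continue
            j, k = name[4:].split("_D")
            levels.setdefault(int(j), {})[int(k)] = data[name]
    highpass = [
        [levels[j][k] for k in sorted(levels[j])] for j in sorted(levels)
    ]
    return ShearletPyramid(lowpass=lowpass, highpass=highpass)


def pad_to_pow2(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad each axis up to the next power of two (min 32).

    Returns the padded image and the original shape, for cropping after
    reconstruction.
    """
    image = _check_image(image)
    h, w = image.shape
    th = max(_MIN_SIZE, 1 << (h - 1).bit_length())
    tw = max(_MIN_SIZE, 1 << (w - 1).bit_length())
    if (th, tw) == (h, w):
        return image, (h, w)
    return np.pad(image, ((0, th - h), (0, tw - w)), mode="reflect"), (h, w)
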