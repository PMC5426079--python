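"""ROI cropping and the three-stage enhancement chain.

Ultrasound frames are cropped to a tumor-centered image (TCI), then
speckle-smoothed with a bilateral filter, contrast-stretched with classical
global histogram equalization, and homogenized with pyramid mean-shift
filtering. Every stage maps uint8 to uint8 and preserves shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_bilateral
from skimage.transform import resize

from ._core import mean_shift_gray
from .config import PreprocessConfig


class InvalidRoiError(ValueError):
    """ROI degenerate or outside the source image."""


@dataclass(frozen=True)
class RoiRect:
    """Rectangular ROI given by two diagonal corners, 0-based half-open.

    Corners may come in any diagonal order; they are normalized so that
    x0 < x1 and y0 < y1.
    """

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        x0, x1 = sorted((int(self.x0), int(self.x1)))
        y0, y1 = sorted((int(self.y0), int(self.y1)))
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "y0", y0)
        object.__setattr__(self, "y1", y1)
        if x1 <= x0 or y1 <= y0:
            raise InvalidRoiError(f"degenerate ROI ({x0},{y0},{x1},{y1})")

    @classmethod
    def from_corners(cls, x0: int, y0: int, x1: int, y1: int) -> "RoiRect":
        return cls(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y1 - self.y0, self.x1 - self.x0)


def to_gray_u8(image: np.ndarray) -> np.ndarray:
    """Coerce an input image to 8-bit grayscale.

    Color images collapse through the ITU-R BT.601 luma weights; float
    images in [0, 1] are rescaled to [0, 255].
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.dtype != np.uint8:
        img = np.asarray(img, dtype=np.float64)
        if img.size and img.max() <= 1.0 and img.min() >= 0.0:
            img = img * 255.0
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def crop_tci(image: np.ndarray, roi: RoiRect) -> np.ndarray:
    """Extract the tumor-centered image: rows [y0, y1), cols [x0, x1)."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
        raise InvalidRoiError(f"ROI {roi} outside {h}x{w} image")
    return img[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()


def bilateral_filter(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Edge-preserving speckle smoothing.

    Pixels are averaged within a square window, weighted jointly by spatial
    distance and intensity difference, so flat regions smooth while steps
    survive.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=np.uint8)
    out = denoise_bilateral(
        img.astype(np.float64) / 255.0,
        win_size=cfg.bilateral_diameter,
        sigma_color=cfg.bilateral_sigma_color / 255.0,
        sigma_spatial=cfg.bilateral_sigma_space,
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def equalization_lut(img: np.ndarray) -> np.ndarray:
    """The classical global histogram-equalization lookup table (uint8).

    LUT[g] = round(255 * (cdf(g) - cdf_min) / (N - cdf_min)); monotone
    non-decreasing by construction. A constant image maps to itself.
    """
    img = np.asarray(img, dtype=np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[hist > 0]
    cdf_min = int(nonzero[0]) if nonzero.size else 0
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # constant image
        return np.arange(256, dtype=np.uint8)
    lut = np.rint(255.0 * (cdf - cdf_min) / denom)
    return np.clip(lut, 0, 255).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Contrast enhancement by classical global histogram equalization."""
    img = np.asarray(img, dtype=np.uint8)
    return equalization_lut(img)[img]


def pyramid_mean_shift(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Mean-shift flattening with a coarse-to-fine pyramid.

    The image is downsampled ``pyramid_levels`` times (factor 2); mean-shift
    filtering runs at the coarsest level, its result is upsampled and used
    to initialize the range value of the filter at the next finer level,
    down to full resolution.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=np.uint8)
    f = img.astype(np.float64)

    levels = [f]
    for _ in range(cfg.meanshift_pyramid_levels):
        prev = levels[-1]
        if min(prev.shape) < 2 * cfg.meanshift_spatial_radius:
            break
        levels.append(resize(prev, (prev.shape[0] // 2, prev.shape[1] // 2),
                             anti_aliasing=True, mode="reflect"))

    init = levels[-1]
    for lev in reversed(levels):
        if init.shape != lev.shape:
            init = resize(init, lev.shape, mode="edge")
        init = mean_shift_gray(
            lev, init, int(cfg.meanshift_spatial_radius),
            float(cfg.meanshift_range_radius), 5,
        )
    out = np.clip(np.rint(init), 0, 255).astype(np.uint8)
    return out


def preprocess_pipeline(
    image: np.ndarray, roi: RoiRect, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Crop then enhance: bilateral -> equalize -> pyramid mean shift."""
    cfg = cfg or PreprocessConfig()
    tci = crop_tci(to_gray_u8(image), roi)
    if cfg.enable_bilateral:
        tci = bilateral_filter(tci, cfg)
    if cfg.enable_equalize:
        tci = equalize_histogram(tci)
    if cfg.enable_meanshift:
        tci = pyramid_mean_shift(tci, cfg)
    return tci
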