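"""Reading and writing images, masks and run artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import to_gray_u8


class UnreadableImageError(IOError):
    """Input image missing or not decodable."""


def read_gray(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF as 8-bit grayscale (color collapses via BT.601)."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (FileNotFoundError, OSError) as exc:
        raise UnreadableImageError(f"cannot read image {path}: {exc}") from exc
    return to_gray_u8(arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask; any nonzero pixel counts as foreground."""
    return (read_gray(path) > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a 0/1 mask as an 8-bit 0/255 PNG."""
    arr = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_gray(path: str | Path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit PNG."""
    Image.fromarray(np.asarray(labels, dtype=np.uint16)).save(path)


def write_overlay(path: str | Path, img: np.ndarray, contour: np.ndarray) -> None:
    """Render the contour in red over the grayscale image."""
    g = np.asarray(img, dtype=np.uint8)
    rgb = np.stack([g, g, g], axis=-1)
    if contour.size:
        rgb[contour[:, 0], contour[:, 1]] = (255, 0, 0)
    Image.fromarray(rgb, mode="RGB").save(path)
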