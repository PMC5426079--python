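"""Binary mask cleanup and contour extraction.

The optimized partition's reference region becomes a binary tumor mask,
smoothed by morphological opening (removes spicules) then closing (fills
holes) with a 5x5 elliptical structuring element, and traced into a closed
contour.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .graph import RegionPartition
from .objective import ReferenceRegion, center_pixel

logger = logging.getLogger(__name__)

# 5x5 discrete ellipse (disk of radius 2, 13 active cells)
KERNEL_5X5_ELLIPSE = disk(2).astype(bool)


class EmptyMaskError(ValueError):
    """Operation undefined on an empty mask."""


def to_binary(partition: RegionPartition, ref: ReferenceRegion) -> np.ndarray:
    """Mask that is 1 exactly on reference-region pixels (uint8 0/1)."""
    return ref.mask.astype(np.uint8)


def morph_open_close(mask: np.ndarray) -> np.ndarray:
    """Opening then closing with the 5x5 elliptical kernel."""
    m = np.asarray(mask).astype(bool)
    opened = ndimage.binary_opening(m, structure=KERNEL_5X5_ELLIPSE)
    closed = ndimage.binary_closing(opened, structure=KERNEL_5X5_ELLIPSE)
    return closed.astype(np.uint8)


def largest_central_component(mask: np.ndarray) -> np.ndarray:
    """Keep one foreground component: the central one, else the largest.

    Guards against morphology splitting the region. An empty mask passes
    through unchanged with a warning.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        logger.warning("empty mask; nothing to keep")
        return m.astype(np.uint8)
    labels, n = ndimage.label(m, structure=np.ones((3, 3), bool))
    if n == 1:
        return m.astype(np.uint8)
    cr, cc = center_pixel(m.shape)
    target = labels[cr, cc]
    if target == 0:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        target = int(sizes.argmax())
    return (labels == target).astype(np.uint8)


# clockwise 8-neighbour offsets, starting north
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary of the foreground, Moore-neighbor traced.

    Returns an (m, 2) array of (row, col); consecutive points are
    8-adjacent and the last point is adjacent to the first. Traces the
    component containing the first foreground pixel in row-major order.
    """
    m = np.asarray(mask).astype(bool)
    fg = np.argwhere(m)
    if fg.size == 0:
        raise EmptyMaskError("cannot trace contour of empty mask")

    def at(p):
        r, c = p
        return 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]

    start = tuple(fg[0])
    p, b = start, (start[0], start[1] - 1)  # west of start is background
    contour: list[tuple[int, int]] = []
    seen: set[tuple] = set()
    while (p, b) not in seen:
        seen.add((p, b))
        contour.append(p)
        if len(contour) > 4 * m.size:  # safety net, unreachable in practice
            raise RuntimeError("contour tracing failed to terminate")
        i0 = _MOORE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for j in range(1, 9):
            off = _MOORE[(i0 + j) % 8]
            cand = (p[0] + off[0], p[1] + off[1])
            if at(cand):
                nxt = cand
                prev_off = _MOORE[(i0 + j - 1) % 8]
                b = (p[0] + prev_off[0], p[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel
            break
        p = nxt
    # drop a duplicated closing point if the cycle re-entered at the start
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.asarray(contour, dtype=np.int64)
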