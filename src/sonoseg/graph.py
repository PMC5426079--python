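"""Graph-based region-merging segmentation with a local-statistics predicate.

The image is a 4- (or 8-) connected pixel graph whose edge weights are
absolute intensity differences. Edges are visited in non-descending weight
order; two regions merge when the difference of their mean intensities does
not exceed the smaller of their internal tolerances sigma(C) + tau(C),

    tau(C) = (k / |C|) * (1 + beta / alpha),   beta = mu(C) / sigma(C),

so the scale parameter ``k`` makes merging easier as it grows, while
``alpha`` makes it harder. The result is a forest of minimum spanning
trees, one per region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import segment_edges


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img


@dataclass(frozen=True)
class RgbParams:
    """Segmenter controls: scale ``k``, stiffness ``alpha``, connectivity."""

    k: float
    alpha: float
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.k <= 0 or self.alpha <= 0:
            raise ValueError("k and alpha must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


class RegionStats:
    """Incremental region statistics: size, mean, population stdev.

    Carries running sum and sum of squares so that merging two regions is
    O(1) and exactly reproduces recomputation from raw pixels (intensities
    are integer-valued, so the float64 sums are exact).
    """

    __slots__ = ("size", "sum", "sumsq")

    def __init__(self, size: int, total: float, total_sq: float) -> None:
        if size < 1:
            raise ValueError("region size must be >= 1")
        self.size = size
        self.sum = total
        self.sumsq = total_sq

    @classmethod
    def from_pixels(cls, values) -> "RegionStats":
        v = np.asarray(values, dtype=np.float64).ravel()
        return cls(v.size, float(v.sum()), float((v * v).sum()))

    @property
    def mean(self) -> float:
        return self.sum / self.size

    @property
    def stdev(self) -> float:
        var = self.sumsq / self.size - self.mean**2
        return math.sqrt(var) if var > 0.0 else 0.0

    def merge(self, other: "RegionStats") -> "RegionStats":
        return RegionStats(
            self.size + other.size, self.sum + other.sum, self.sumsq + other.sumsq
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionStats(size={self.size}, mean={self.mean:.3f}, stdev={self.stdev:.3f})"


def tau(stats: RegionStats, params: RgbParams) -> float:
    """Merge-tolerance threshold of a region.

    ``beta = mean/stdev`` is taken as 0 for a uniform region (stdev 0), so
    tau reduces to the pure size threshold ``k/|C|``.
    """
    sig = stats.stdev
    beta = stats.mean / sig if sig > 0.0 else 0.0
    return (params.k / stats.size) * (1.0 + beta / params.alpha)


def merge_predicate(s1: RegionStats, s2: RegionStats, params: RgbParams) -> bool:
    """True iff the boundary between the two regions may be eliminated.

    Merging is allowed when |mu1 - mu2| <= min(sigma1 + tau1, sigma2 + tau2);
    symmetric in its arguments.
    """
    dif = abs(s1.mean - s2.mean)
    mint = min(s1.stdev + tau(s1, params), s2.stdev + tau(s2, params))
    return dif <= mint


def build_graph(img: np.ndarray, connectivity: int = 4):
    """Edge arrays (a, b, weight) of the pixel-adjacency graph.

    Edges appear in construction order: pixels row-major, and per pixel the
    right edge precedes the down edge (then, under 8-connectivity, the
    down-right and down-left diagonals). Weight = |I_a - I_b|.
    """
    img = _validate_image(img)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    h, w = img.shape
    idx = np.arange(h * w).reshape(h, w)
    rows, cols = np.indices((h, w))

    # neighbour offsets in per-pixel construction order
    if connectivity == 4:
        offsets = [(0, 1), (1, 0)]
    else:
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]

    slots_a, slots_b, slots_ok = [], [], []
    for dr, dc in offsets:
        ok = (rows + dr < h) & (rows + dr >= 0) & (cols + dc < w) & (cols + dc >= 0)
        slots_a.append(idx)
        slots_b.append(idx + dr * w + dc)
        slots_ok.append(ok)
    a = np.stack([s.ravel() for s in slots_a], axis=1).ravel()
    b = np.stack([s.ravel() for s in slots_b], axis=1).ravel()
    ok = np.stack([s.ravel() for s in slots_ok], axis=1).ravel()
    a, b = a[ok], b[ok]
    flat = img.astype(np.float64).ravel()
    weight = np.abs(flat[a] - flat[b])
    return a.astype(np.int64), b.astype(np.int64), weight


@dataclass
class RegionPartition:
    """A labelling of the image into regions plus per-region statistics.

    Labels are canonical: 0..R-1 in order of first appearance in row-major
    scan, so identical inputs always yield identical label maps.
    """

    labels: np.ndarray                     # int32 HxW
    regions: dict[int, RegionStats] = field(repr=False)

    @classmethod
    def from_roots(cls, roots: np.ndarray, img: np.ndarray) -> "RegionPartition":
        h, w = img.shape
        _, canonical = np.unique(roots, return_inverse=True)
        # reorder so labels follow first occurrence in the row-major scan
        first = np.full(canonical.max() + 1, roots.size, dtype=np.int64)
        np.minimum.at(first, canonical, np.arange(roots.size))
        rank = np.argsort(np.argsort(first))
        labels = rank[canonical].astype(np.int32)

        flat = img.astype(np.float64).ravel()
        n = int(labels.max()) + 1
        sizes = np.bincount(labels, minlength=n)
        sums = np.bincount(labels, weights=flat, minlength=n)
        sumsqs = np.bincount(labels, weights=flat * flat, minlength=n)
        regions = {
            lab: RegionStats(int(sizes[lab]), float(sums[lab]), float(sumsqs[lab]))
            for lab in range(n)
        }
        return cls(labels=labels.reshape(h, w), regions=regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (lab, st.size, st.mean, st.stdev)
            for lab, st in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["label", "size", "mean", "stdev"])

    def to_label_image(self) -> np.ndarray:
        if self.n_regions > 65535:
            raise ValueError("too many regions for a 16-bit label image")
        return self.labels.astype(np.uint16)


def segment(img: np.ndarray, params: RgbParams) -> RegionPartition:
    """Segment an image by sorted-edge region merging.

    The edge sort is stable with ties broken by construction order, and the
    merge decision at each edge uses the statistics of the regions as they
    exist at that moment, so the partition is deterministic for fixed input.
    """
    img = _validate_image(img)
    a, b, weight = build_graph(img, params.connectivity)
    order = np.argsort(weight, kind="stable").astype(np.int64)
    roots = segment_edges(
        img.astype(np.float64).ravel(), a, b, order, float(params.k), float(params.alpha)
    )
    return RegionPartition.from_roots(roots, img)


def region_containing(partition: RegionPartition, pixel: tuple[int, int]) -> int:
    """Label of the region owning ``pixel`` = (row, col)."""
    r, c = pixel
    h, w = partition.labels.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"pixel {pixel} outside {h}x{w} image")
    return int(partition.labels[r, c])
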