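"""Multi-term fitness of a candidate segmentation.

The region holding the TCI's central pixel (the *reference region*) is the
candidate tumor. Its quality is scored by three terms:

* ``V_B`` — between-class variance: size-weighted squared contrast between
  the reference region and each region touching it (larger is better);
* ``V_W`` — within-class variance: arctan-damped intensity variance inside
  the reference region, divided by its area fraction so that shrinking the
  region cannot cheat the term (smaller is better);
* ``G_A`` — mean Sobel gradient magnitude over the reference region's inner
  boundary (larger is better, pulling the contour onto real edges).

Each term is normalized by its mean over the initial particle swarm and the
three are combined as F_O = a*V_B/f_B - b*V_W/f_W + c*G_A/f_A, which the
optimizer maximizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import ObjectiveWeights
from .graph import RegionPartition, RegionStats, RgbParams, build_graph, segment
from ._core import segment_edges

logger = logging.getLogger(__name__)

# 4-connectivity structuring element, used for both adjacency and boundary
_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ReferenceRegion:
    """The candidate tumor region: the one containing the TCI center."""

    label: int
    mask: np.ndarray  # bool HxW
    stats: RegionStats


@dataclass
class NormalizationFactors:
    """Swarm-mean values of the three raw terms; fixed once per image."""

    f_b: float
    f_w: float
    f_a: float


@dataclass
class ObjectiveBreakdown:
    """Raw term values and (when factors are known) the combined fitness."""

    v_b: float
    v_w: float
    g_a: float
    f_o: float | None = None


def center_pixel(shape: tuple[int, int]) -> tuple[int, int]:
    return (shape[0] // 2, shape[1] // 2)


def extract_reference_region(partition: RegionPartition) -> ReferenceRegion:
    """Region containing the central pixel (floor convention)."""
    r, c = center_pixel(partition.labels.shape)
    label = int(partition.labels[r, c])
    mask = partition.labels == label
    return ReferenceRegion(label=label, mask=mask, stats=partition.regions[label])


def adjacent_regions(partition: RegionPartition, ref: ReferenceRegion) -> set[int]:
    """Labels of regions with a pixel 4-adjacent to the reference region."""
    ring = ndimage.binary_dilation(ref.mask, structure=_PLUS) & ~ref.mask
    return set(int(v) for v in np.unique(partition.labels[ring]))


def between_class_variance(
    partition: RegionPartition, ref: ReferenceRegion, tci_size: int
) -> float:
    """V_B = sum over adjacent regions of P(C_i) * (mu_i - mu_ref)^2."""
    mu_ref = ref.stats.mean
    v_b = 0.0
    for lab in adjacent_regions(partition, ref):
        st = partition.regions[lab]
        v_b += (st.size / tci_size) * (st.mean - mu_ref) ** 2
    return v_b


def within_class_variance(
    img: np.ndarray, ref: ReferenceRegion, tci_size: int, form: str = "divide"
) -> float:
    """Arctan-damped reference-region variance, weighted by area fraction.

    ``form="divide"`` (default) computes arctan(var)/P(C_ref); the
    alternative ``"multiply"`` computes arctan(var)*P(C_ref) and exists for
    sensitivity checks only.
    """
    vals = np.asarray(img, dtype=np.float64)[ref.mask]
    var = float(np.mean((vals - vals.mean()) ** 2)) if vals.size else 0.0
    p = ref.stats.size / tci_size
    if form == "divide":
        return math.atan(var) / p
    return math.atan(var) * p


def boundary_pixels(ref: ReferenceRegion) -> np.ndarray:
    """Inner 4-boundary of the region as an (m, 2) array of (row, col).

    A member pixel is boundary if any 4-neighbor lies outside the region;
    the image border counts as outside.
    """
    interior = ndimage.binary_erosion(ref.mask, structure=_PLUS, border_value=0)
    edge = ref.mask & ~interior
    return np.argwhere(edge)


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(gx^2 + gy^2), replicate padding."""
    f = np.asarray(img, dtype=np.float64)
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def average_gradient(
    img: np.ndarray, ref: ReferenceRegion, grad: np.ndarray | None = None
) -> float:
    """G_A: mean Sobel magnitude over the reference-region boundary."""
    if grad is None:
        grad = sobel_magnitude(img)
    edge = boundary_pixels(ref)
    return float(grad[edge[:, 0], edge[:, 1]].mean())


def normalization_factors(
    term_samples: list[tuple[float, float, float]],
) -> NormalizationFactors:
    """Arithmetic means of (V_B, V_W, G_A) over the initial swarm.

    A zero mean (degenerate image) is replaced by 1 so later divisions stay
    defined; a warning is logged when that happens.
    """
    if not term_samples:
        raise ValueError("need at least one term sample")
    arr = np.asarray(term_samples, dtype=np.float64)
    means = arr.mean(axis=0)
    out = []
    for name, m in zip(("f_B", "f_W", "f_A"), means):
        if m == 0.0:
            logger.warning("normalization factor %s is zero; using 1", name)
            m = 1.0
        out.append(float(m))
    return NormalizationFactors(*out)


def combined_objective(
    v_b: float,
    v_w: float,
    g_a: float,
    factors: NormalizationFactors,
    weights: ObjectiveWeights | None = None,
) -> float:
    """F_O = a*V_B/f_B - b*V_W/f_W + c*G_A/f_A (maximized)."""
    w = weights or ObjectiveWeights()
    return w.a * v_b / factors.f_b - w.b * v_w / factors.f_w + w.c * g_a / factors.f_a


def evaluate_candidate(
    img: np.ndarray,
    params: RgbParams,
    factors: NormalizationFactors | None = None,
    weights: ObjectiveWeights | None = None,
    vw_form: str = "divide",
) -> ObjectiveBreakdown:
    """Segment with (k, alpha) and score the resulting reference region.

    When ``factors`` is None (the pre-normalization pass) the combined
    fitness is left unset.
    """
    partition = segment(img, params)
    return score_partition(img, partition, factors, weights, vw_form=vw_form)


def score_partition(
    img: np.ndarray,
    partition: RegionPartition,
    factors: NormalizationFactors | None = None,
    weights: ObjectiveWeights | None = None,
    grad: np.ndarray | None = None,
    vw_form: str = "divide",
) -> ObjectiveBreakdown:
    img = np.asarray(img)
    tci_size = img.size
    ref = extract_reference_region(partition)
    v_b = between_class_variance(partition, ref, tci_size)
    v_w = within_class_variance(img, ref, tci_size, form=vw_form)
    g_a = average_gradient(img, ref, grad=grad)
    f_o = None
    if factors is not None:
        f_o = combined_objective(v_b, v_w, g_a, factors, weights)
    return ObjectiveBreakdown(v_b=v_b, v_w=v_w, g_a=g_a, f_o=f_o)


class ObjectiveEvaluator:
    """Cached per-image fitness evaluation for the particle swarm.

    Precomputes the pixel graph, the edge traversal order and the Sobel
    magnitude once per image; each distinct (k, alpha) is segmented and
    scored at most once. The normalization factors are set exactly once,
    from the raw terms of the initial swarm positions.
    """

    def __init__(
        self,
        img: np.ndarray,
        weights: ObjectiveWeights | None = None,
        connectivity: int = 4,
        vw_form: str = "divide",
    ) -> None:
        self.img = np.asarray(img, dtype=np.uint8)
        self.weights = weights or ObjectiveWeights()
        self.connectivity = connectivity
        self.vw_form = vw_form
        self._a, self._b, w = build_graph(self.img, connectivity)
        self._order = np.argsort(w, kind="stable").astype(np.int64)
        self._flat = self.img.astype(np.float64).ravel()
        self._grad = sobel_magnitude(self.img)
        self.factors: NormalizationFactors | None = None
        self._cache: dict[tuple[float, float], ObjectiveBreakdown] = {}
        self.n_evaluations = 0

    def partition(self, k: float, alpha: float) -> RegionPartition:
        roots = segment_edges(self._flat, self._a, self._b, self._order,
                              float(k), float(alpha))
        return RegionPartition.from_roots(roots, self.img)

    def breakdown(self, k: float, alpha: float) -> ObjectiveBreakdown:
        key = (float(k), float(alpha))
        hit = self._cache.get(key)
        if hit is None:
            part = self.partition(k, alpha)
            hit = score_partition(
                self.img, part, factors=None, grad=self._grad, vw_form=self.vw_form
            )
            self._cache[key] = hit
            self.n_evaluations += 1
        return hit

    def set_normalization(self, positions: np.ndarray) -> NormalizationFactors:
        if self.factors is not None:
            raise RuntimeError("normalization factors already set for this image")
        samples = [
            (b.v_b, b.v_w, b.g_a)
            for b in (self.breakdown(k, a) for k, a in np.asarray(positions))
        ]
        self.factors = normalization_factors(samples)
        return self.factors

    def __call__(self, position) -> float:
        if self.factors is None:
            raise RuntimeError("call set_normalization before fitness evaluation")
        k, alpha = float(position[0]), float(position[1])
        b = self.breakdown(k, alpha)
        return combined_objective(b.v_b, b.v_w, b.g_a, self.factors, self.weights)
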