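"""Segmentation quality metrics against a ground-truth mask.

Two families: volume fractions (TPVF/FPVF/FNVF, percentages of the truth
area) and the averaged radial error (ARE), which casts ``n_rays`` rays from
the truth region's center and averages the normalized distance between the
outermost truth and segmentation boundary crossings:

    ARE = (1/n) * sum_i |C_s(i) - C_r(i)| / |C_r(i) - C_o| * 100%.

TPVF + FNVF = 100 is an algebraic identity; FPVF is uncapped and exceeds
100% when the segmentation grossly over-covers the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Metric undefined (empty truth mask or fully degenerate rays)."""


@dataclass
class MetricsReport:
    are: float
    tpvf: float
    fpvf: float
    fnvf: float
    n_rays: int = 180

    def to_dict(self) -> dict:
        return asdict(self)


def volume_fractions(truth: np.ndarray, seg: np.ndarray) -> tuple[float, float, float]:
    """(TPVF, FPVF, FNVF) in percent of the truth area."""
    t = np.asarray(truth).astype(bool)
    s = np.asarray(seg).astype(bool)
    if t.shape != s.shape:
        raise ValueError("masks must have the same shape")
    a_m = int(t.sum())
    if a_m == 0:
        raise UndefinedMetricError("truth mask is empty")
    a_n = int(s.sum())
    inter = int((t & s).sum())
    tpvf = inter / a_m * 100.0
    fpvf = (a_n - inter) / a_m * 100.0
    fnvf = (a_m - inter) / a_m * 100.0
    return tpvf, fpvf, fnvf


def region_center(truth: np.ndarray) -> tuple[int, int]:
    """Foreground centroid, rounded; snapped to the nearest foreground
    pixel when the rounded centroid lands on background (non-convex truth).
    """
    t = np.asarray(truth).astype(bool)
    fg = np.argwhere(t)
    if fg.size == 0:
        raise UndefinedMetricError("truth mask is empty")
    cr, cc = np.rint(fg.mean(axis=0)).astype(int)
    if not t[cr, cc]:
        d2 = ((fg - (cr, cc)) ** 2).sum(axis=1)
        cr, cc = fg[int(d2.argmin())]
        logger.warning("centroid on background; snapped to (%d, %d)", cr, cc)
    return int(cr), int(cc)


def radial_crossings(
    mask: np.ndarray, center: tuple[int, int], n_rays: int = 180, step: float = 0.25
) -> np.ndarray:
    """Radius of the outermost inside->outside transition along each ray.

    Rays leave ``center`` at angles 2*pi*i/n_rays and are sampled every
    ``step`` pixels (nearest-pixel lookup, outside the image = background);
    the reported radius is the midpoint of the last inside/outside sample
    pair. A ray whose origin is background gets radius 0 with a warning.
    """
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    cr, cc = center
    if not m[cr, cc]:
        logger.warning("ray origin (%d, %d) is background", cr, cc)
    t_max = float(np.hypot(h, w)) + 1.0
    # sample at half-step offsets so pixel edges (at .5 coordinates) fall
    # between samples; round half up for a direction-symmetric lookup
    ts = (np.arange(int(t_max / step)) + 0.5) * step
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays

    radii = np.zeros(n_rays)
    for i, th in enumerate(angles):
        ys = cr + ts * np.sin(th)
        xs = cc + ts * np.cos(th)
        rr = np.floor(ys + 0.5).astype(int)
        ccs = np.floor(xs + 0.5).astype(int)
        inside = (rr >= 0) & (rr < h) & (ccs >= 0) & (ccs < w)
        vals = np.zeros(ts.size, dtype=bool)
        vals[inside] = m[rr[inside], ccs[inside]]
        if not vals[0]:
            radii[i] = 0.0
            continue
        trans = np.flatnonzero(vals[:-1] & ~vals[1:])
        if trans.size == 0:  # never leaves the mask before the border pad
            radii[i] = ts[-1]
        else:
            j = trans[-1]
            radii[i] = 0.5 * (ts[j] + ts[j + 1])
    return radii


def averaged_radial_error(
    truth: np.ndarray, seg: np.ndarray, n_rays: int = 180
) -> float:
    """ARE in percent; the center comes from the truth mask and is shared
    by both contours. Rays with zero truth radius are skipped (warning)."""
    center = region_center(truth)
    r_truth = radial_crossings(truth, center, n_rays)
    r_seg = radial_crossings(seg, center, n_rays)
    ok = r_truth > 0
    if not ok.any():
        raise UndefinedMetricError("all rays degenerate (zero truth radius)")
    if not ok.all():
        logger.warning("skipping %d rays with zero truth radius", int((~ok).sum()))
    return float(np.mean(np.abs(r_seg[ok] - r_truth[ok]) / r_truth[ok]) * 100.0)


def evaluate_masks(truth: np.ndarray, seg: np.ndarray, n_rays: int = 180) -> MetricsReport:
    """Full report: ARE plus the three volume fractions."""
    tpvf, fpvf, fnvf = volume_fractions(truth, seg)
    are = averaged_radial_error(truth, seg, n_rays=n_rays)
    return MetricsReport(are=are, tpvf=tpvf, fpvf=fpvf, fnvf=fnvf, n_rays=n_rays)
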