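"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: region statistics are recomputed from raw pixel sets at
every merge decision (via the statistics stdlib module, not the package's
incremental updates), and the union-find is a plain membership list.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def reference_segment(img: np.ndarray, k: float, alpha: float) -> np.ndarray:
    """Sorted-edge region merging, recomputing stats from scratch each step.

    Returns a canonical label map (labels numbered by first row-major
    occurrence) for comparison with the production segmenter.
    """
    img = np.asarray(img)
    h, w = img.shape
    flat = [float(v) for v in img.ravel()]

    # edges in construction order: row-major, right edge then down edge
    edges = []
    for r in range(h):
        for c in range(w):
            i = r * w + c
            if c + 1 < w:
                edges.append((abs(flat[i] - flat[i + 1]), i, i + 1))
            if r + 1 < h:
                edges.append((abs(flat[i] - flat[i + w]), i, i + w))
    edges.sort(key=lambda e: e[0])  # python sort is stable

    member = list(range(h * w))          # pixel -> region id
    pixels = {i: [i] for i in range(h * w)}  # region id -> pixel list

    def stats(rid):
        vals = [flat[p] for p in pixels[rid]]
        mu = statistics.fmean(vals)
        sigma = statistics.pstdev(vals)
        return len(vals), mu, sigma

    def tau(n, mu, sigma):
        beta = mu / sigma if sigma > 0 else 0.0
        return (k / n) * (1.0 + beta / alpha)

    for _, a, b in edges:
        ra, rb = member[a], member[b]
        if ra == rb:
            continue
        na, mua, sa = stats(ra)
        nb, mub, sb = stats(rb)
        dif = abs(mua - mub)
        mint = min(sa + tau(na, mua, sa), sb + tau(nb, mub, sb))
        if dif <= mint:
            for p in pixels[rb]:
                member[p] = ra
            pixels[ra].extend(pixels[rb])
            del pixels[rb]

    return canonical_labels(np.asarray(member).reshape(h, w))


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel regions as 0..R-1 in order of first row-major occurrence."""
    out = np.empty_like(labels, dtype=np.int64)
    mapping: dict = {}
    flat = labels.ravel()
    oflat = out.ravel()
    for i, v in enumerate(flat):
        key = int(v)
        if key not in mapping:
            mapping[key] = len(mapping)
        oflat[i] = mapping[key]
    return out


def brute_force_erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion by direct structuring-element placement (outside=0)."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    sh, sw = se.shape
    cy, cx = sh // 2, sw // 2
    out = np.zeros_like(m)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(sh):
                for dc in range(sw):
                    if not se[dr, dc]:
                        continue
                    rr, cc = r + dr - cy, c + dc - cx
                    if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def brute_force_dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    sh, sw = se.shape
    cy, cx = sh // 2, sw // 2
    out = np.zeros_like(m)
    for r in range(h):
        for c in range(w):
            hit = False
            for dr in range(sh):
                for dc in range(sw):
                    if not se[dr, dc]:
                        continue
                    rr, cc = r - (dr - cy), c - (dc - cx)
                    if 0 <= rr < h and 0 <= cc < w and m[rr, cc]:
                        hit = True
                        break
                if hit:
                    break
            out[r, c] = hit
    return out


def coverage_disk(shape, center, radius, supersample: int = 8) -> np.ndarray:
    """Digitize a disk by area coverage: pixel on iff >= half inside.

    Represents an analytic circle on the grid with ~zero radial bias,
    unlike the center-in-circle rule whose diagonal deficit shifts the
    apparent radius by up to ~0.3 px.
    """
    h, w = shape
    ss = supersample
    yy, xx = np.mgrid[0 : h * ss, 0 : w * ss]
    fine = ((yy + 0.5) / ss - 0.5 - center[0]) ** 2 + (
        (xx + 0.5) / ss - 0.5 - center[1]
    ) ** 2 <= radius * radius
    cov = fine.reshape(h, ss, w, ss).mean(axis=(1, 3))
    return (cov >= 0.5).astype(np.uint8)
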