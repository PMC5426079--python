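"""Numba kernels for the inner loops.

The merge loop of the graph segmenter runs once per particle per PSO
generation (thousands of times per image), and the mean-shift filter visits
a full spatial window per pixel; both are jitted. The arithmetic here
mirrors the Python-level :func:`sonoseg.graph.tau` /
:func:`sonoseg.graph.merge_predicate` exactly — any change must be made in
both places.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent: np.ndarray, i: int) -> int:
    root = i
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def segment_edges(
    intens: np.ndarray,   # float64, flat pixel intensities
    ea: np.ndarray,       # int64 edge endpoints
    eb: np.ndarray,
    order: np.ndarray,    # int64 traversal order (stable sort by weight)
    k: float,
    alpha: float,
) -> np.ndarray:
    """Union-find region merging over pre-sorted edges.

    Region statistics are carried as running (count, sum, sum of squares)
    and updated in O(1) per merge; sums of integer-valued intensities are
    exact in float64, so the incremental statistics equal a recomputation
    from raw pixels.
    Returns the root pixel index of each pixel's region.
    """
    n = intens.size
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    s1 = intens.copy()
    s2 = intens * intens

    for t in range(order.size):
        e = order[t]
        ra = _find(parent, ea[e])
        rb = _find(parent, eb[e])
        if ra == rb:
            continue
        mu_a = s1[ra] / size[ra]
        var_a = s2[ra] / size[ra] - mu_a * mu_a
        sig_a = np.sqrt(var_a) if var_a > 0.0 else 0.0
        mu_b = s1[rb] / size[rb]
        var_b = s2[rb] / size[rb] - mu_b * mu_b
        sig_b = np.sqrt(var_b) if var_b > 0.0 else 0.0

        beta_a = mu_a / sig_a if sig_a > 0.0 else 0.0
        beta_b = mu_b / sig_b if sig_b > 0.0 else 0.0
        tau_a = (k / size[ra]) * (1.0 + beta_a / alpha)
        tau_b = (k / size[rb]) * (1.0 + beta_b / alpha)

        dif = abs(mu_a - mu_b)
        mint = min(sig_a + tau_a, sig_b + tau_b)
        if dif <= mint:
            parent[rb] = ra
            size[ra] += size[rb]
            s1[ra] += s1[rb]
            s2[ra] += s2[rb]

    roots = np.empty(n, dtype=np.int64)
    for i in range(n):
        roots[i] = _find(parent, i)
    return roots


@njit(cache=True)
def mean_shift_gray(
    img: np.ndarray,      # float64 HxW
    init_v: np.ndarray,   # float64 HxW initial range values
    sp: int,
    sr: float,
    max_iter: int,
) -> np.ndarray:
    """Joint spatial-range mean-shift filtering of a grayscale image.

    For each pixel, the (x, y, v) state iterates toward the local mode:
    pixels inside the (2*sp+1)^2 window whose intensity lies within sr of
    the current value are averaged. The converged range value is written
    out, flattening homogeneous patches while leaving steps larger than sr
    untouched.
    """
    h, w = img.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            x = float(c)
            y = float(r)
            v = init_v[r, c]
            for _ in range(max_iter):
                rc = int(round(y))
                cc0 = int(round(x))
                r0 = max(0, rc - sp)
                r1 = min(h - 1, rc + sp)
                c0 = max(0, cc0 - sp)
                c1 = min(w - 1, cc0 + sp)
                sx = 0.0
                sy = 0.0
                sv = 0.0
                cnt = 0
                for rr in range(r0, r1 + 1):
                    for cc in range(c0, c1 + 1):
                        val = img[rr, cc]
                        if abs(val - v) <= sr:
                            sx += cc
                            sy += rr
                            sv += val
                            cnt += 1
                if cnt == 0:
                    break
                nx = sx / cnt
                ny = sy / cnt
                nv = sv / cnt
                shift = abs(nx - x) + abs(ny - y) + abs(nv - v)
                x = nx
                y = ny
                v = nv
                if shift < 0.5:
                    break
            out[r, c] = v
    return out
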