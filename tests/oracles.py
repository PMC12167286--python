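"""Brute-force metric oracles, deliberately independent of the package.

Used by the unit tests and the acceptance suite to cross-check DSC and NSD
by exhaustive enumeration over pixels and boundary-point pairs.
"""

import numpy as np


def brute_dsc(p: np.ndarray, g: np.ndarray) -> float:
    inter = sum(1 for idx in np.ndindex(p.shape) if p[idx] and g[idx])
    tot = int(p.sum()) + int(g.sum())
    return float("nan") if tot == 0 else 2.0 * inter / tot


def brute_boundary(region: np.ndarray) -> list[tuple[int, int]]:
    pts = []
    h, w = region.shape
    for y in range(h):
        for x in range(w):
            if not region[y, x]:
                continue
            edge = False
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if ny < 0 or nx < 0 or ny >= h or nx >= w or not region[ny, nx]:
                        edge = True
            if edge:
                pts.append((y, x))
    return pts


def brute_nsd(p: np.ndarray, g: np.ndarray, tol: float) -> float:
    bp, bg = brute_boundary(p), brute_boundary(g)
    if not bp and not bg:
        return float("nan")

    def near(pt, pts):
        return any((pt[0] - q[0]) ** 2 + (pt[1] - q[1]) ** 2 <= tol**2
                   for q in pts)

    hits = sum(near(pt, bg) for pt in bp) + sum(near(pt, bp) for pt in bg)
    return hits / (len(bp) + len(bg))
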