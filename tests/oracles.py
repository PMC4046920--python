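"""Independent brute-force oracles for morphology and rank statistics.

These are deliberately naive reference implementations — iterative geodesic
dilation, per-pixel sort-and-middle medians, exhaustive enumeration of rank
arrangements — kept separate from the package so agreement tests compare
two genuinely independent routes.
"""

from itertools import combinations

import numpy as np


def brute_median_filter(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel sort-and-middle median over the (2r+1)^2 window,
    edge-replicated."""
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, radius, mode="edge")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1]
            out[r, c] = np.median(win)
    return out


def _dilate8(img: np.ndarray) -> np.ndarray:
    """Grayscale dilation with the 3x3 (8-connected) structuring element."""
    p = np.pad(img, 1, mode="constant", constant_values=-np.inf)
    out = img.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out = np.maximum(
                out, p[1 + dr : 1 + dr + img.shape[0], 1 + dc : 1 + dc + img.shape[1]]
            )
    return out


def geodesic_reconstruction(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reconstruction by dilation: iterate rec = min(dilate(rec), mask) to a
    fixed point."""
    rec = np.asarray(marker, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.minimum(_dilate8(rec), mask)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def regional_maxima(img: np.ndarray) -> np.ndarray:
    """Plateau enumeration: flood-fill each constant-value 8-connected
    plateau and mark it if no neighbor exceeds its value."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if visited[r0, c0]:
                continue
            v = img[r0, c0]
            stack = [(r0, c0)]
            plateau = []
            visited[r0, c0] = True
            is_max = True
            while stack:
                r, c = stack.pop()
                plateau.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w):
                            continue
                        if img[rr, cc] == v:
                            if not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                        elif img[rr, cc] > v:
                            is_max = False
            if is_max:
                for r, c in plateau:
                    out[r, c] = True
    return out


def brute_extended_maxima(img: np.ndarray, h: float) -> np.ndarray:
    """Regional maxima of the brute-force h-maxima transform."""
    f = np.asarray(img, dtype=float)
    rec = geodesic_reconstruction(f - h, f)
    return regional_maxima(rec)


def exact_mann_whitney_p(x, y) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney p by enumeration of all C(n1+n2, n1)
    assignments of the pooled ranks to group x. Tie-free samples only.

    Returns (U_x, p). Two-tailed p doubles the smaller tail probability of
    the observed U (capped at 1), matching the standard exact convention.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n1 + n2, "tie-free samples required"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - n1 * (n1 + 1) / 2

    us = []
    all_ranks = list(range(1, n1 + n2 + 1))
    for comb in combinations(all_ranks, n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.asarray(us, dtype=float)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))
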