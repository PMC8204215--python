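"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (BFS flood fill,
hypergeometric enumeration, exhaustive scans) without calling the package's
own implementations, so they can serve as cross-checks.
"""

import math
from collections import deque

import numpy as np


def flood_fill_components(uncovered: np.ndarray, wrap_columns: bool) -> list[set]:
    """8-connected components of True cells; columns optionally wrap."""
    nz, na = uncovered.shape
    seen = np.zeros_like(uncovered, dtype=bool)
    comps = []
    for i0 in range(nz):
        for j0 in range(na):
            if not uncovered[i0, j0] or seen[i0, j0]:
                continue
            comp = set()
            q = deque([(i0, j0)])
            seen[i0, j0] = True
            while q:
                i, j = q.popleft()
                comp.add((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ni, nj = i + di, j + dj
                        if not (0 <= ni < nz):
                            continue
                        if wrap_columns:
                            nj %= na
                        elif not (0 <= nj < na):
                            continue
                        if uncovered[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            q.append((ni, nj))
            comps.append(comp)
    return comps


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher p by full enumeration of margin-fixed tables.

    Returns (p, total_probability) so callers can also check the
    hypergeometric probabilities sum to 1.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(table with top-left = x)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    p = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        total += px
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0), total


def exhaustive_surface_scan(aline, params, intensity_max) -> int | None:
    """Surface detection by an explicit per-sample scan (no vectorisation)."""
    aline = np.asarray(aline, dtype=float)
    n = aline.size
    h = params.smoothing_halfwidth
    smooth = np.empty(n)
    for r in range(n):
        lo, hi = max(0, r - h), min(n, r + h + 1)
        # replicate 'nearest' edge handling of a centred moving average
        window = []
        for k in range(r - h, r + h + 1):
            window.append(aline[min(max(k, 0), n - 1)])
        smooth[r] = np.mean(window)
    total = aline.sum()
    for r in range(n):
        if r == 0:
            grad = smooth[1] - smooth[0]
        elif r == n - 1:
            grad = smooth[-1] - smooth[-2]
        else:
            grad = (smooth[r + 1] - smooth[r - 1]) / 2.0
        cum_before = aline[:r].sum()
        if (
            grad >= params.surface_gradient_min * intensity_max
            and aline[r] >= params.tissue_intensity_min * intensity_max
            and cum_before <= params.cumsum_lumen_max * total
        ):
            return r
    return None


def mann_whitney_u_pairs(a, b) -> float:
    """U1 by explicit double loop over all pairs."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
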