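"""Independent brute-force reference implementations used only by tests.

Everything here is written from the mathematical definitions with plain
loops, deliberately sharing no code with the package internals.
"""

import heapq

import numpy as np
from scipy import stats


# ---------------------------------------------------------------- morphology
def brute_dilate(f, offsets):
    """max f(x-u, y-v) over in-domain samples, straight from the definition."""
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    out = np.empty_like(f)
    for x in range(h):
        for y in range(w):
            best = -np.inf
            for u, v in offsets:
                xx, yy = x - u, y - v
                if 0 <= xx < h and 0 <= yy < w:
                    best = max(best, f[xx, yy])
            out[x, y] = best
    return out


def brute_erode(f, offsets):
    """min f(x+u, y+v) over in-domain samples."""
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    out = np.empty_like(f)
    for x in range(h):
        for y in range(w):
            best = np.inf
            for u, v in offsets:
                xx, yy = x + u, y + v
                if 0 <= xx < h and 0 <= yy < w:
                    best = min(best, f[xx, yy])
            out[x, y] = best
    return out


def brute_reconstruct_dilation(marker, mask, offsets):
    """Iterate min(dilate(marker), mask) with the brute-force dilation until
    the fixed point."""
    cur = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.minimum(brute_dilate(cur, offsets), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def brute_reconstruct_erosion(marker, mask, offsets):
    cur = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.maximum(brute_erode(cur, offsets), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def brute_median(f, size):
    """Sort-based median over the in-domain window (even counts average the
    two middle order statistics)."""
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    m = size // 2
    out = np.empty_like(f)
    for x in range(h):
        for y in range(w):
            vals = sorted(
                f[xx, yy]
                for xx in range(max(0, x - m), min(h, x + m + 1))
                for yy in range(max(0, y - m), min(w, y + m + 1))
            )
            k = len(vals)
            out[x, y] = vals[k // 2] if k % 2 else 0.5 * (vals[k // 2 - 1] + vals[k // 2])
    return out


# -------------------------------------------------------------------- minima
def _neighbors(x, y, h, w, connectivity):
    if connectivity == 4:
        steps = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        steps = tuple((u, v) for u in (-1, 0, 1) for v in (-1, 0, 1) if (u, v) != (0, 0))
    for u, v in steps:
        xx, yy = x + u, y + v
        if 0 <= xx < h and 0 <= yy < w:
            yield xx, yy


def flood_regional_minima(f, connectivity=8):
    """Flood-check oracle: a plateau is a regional minimum iff every exterior
    neighbor is strictly greater."""
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for x in range(h):
        for y in range(w):
            if seen[x, y]:
                continue
            v = f[x, y]
            plateau = [(x, y)]
            seen[x, y] = True
            stack = [(x, y)]
            is_min = True
            while stack:
                cx, cy = stack.pop()
                for nx, ny in _neighbors(cx, cy, h, w, connectivity):
                    if f[nx, ny] == v:
                        if not seen[nx, ny]:
                            seen[nx, ny] = True
                            plateau.append((nx, ny))
                            stack.append((nx, ny))
                    elif f[nx, ny] < v:
                        is_min = False
            if is_min:
                for px, py in plateau:
                    out[px, py] = True
    return out


def minima_dynamics(f, connectivity=8):
    """For every regional minimum return (plateau mask, dynamic).

    The dynamic is the smallest climb needed to escape to a strictly lower
    pixel (infinite for a global minimum), computed by a minimax-path
    Dijkstra search from the plateau.
    """
    f = np.asarray(f, dtype=float)
    h, w = f.shape
    minima = flood_regional_minima(f, connectivity)
    from scipy import ndimage

    structure = (
        np.ones((3, 3), bool)
        if connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    )
    lab, n = ndimage.label(minima, structure=structure)
    results = []
    for i in range(1, n + 1):
        comp = lab == i
        v = f[comp][0]
        best = np.full((h, w), np.inf)
        heap = []
        for x, y in zip(*np.nonzero(comp)):
            best[x, y] = v
            heapq.heappush(heap, (v, x, y))
        dyn = np.inf
        while heap:
            cost, x, y = heapq.heappop(heap)
            if cost > best[x, y]:
                continue
            if f[x, y] < v:
                dyn = cost - v
                break
            for nx, ny in _neighbors(x, y, h, w, connectivity):
                ncost = max(cost, f[nx, ny])
                if ncost < best[nx, ny]:
                    best[nx, ny] = ncost
                    heapq.heappush(heap, (ncost, nx, ny))
        results.append((comp, dyn))
    return results


# ---------------------------------------------------------------------- otsu
def brute_otsu(counts):
    """Exhaustive between-class-variance scan; returns (T, sigma2 array)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    sigma2 = np.full(256, np.nan)
    for t in range(256):
        n1 = counts[: t + 1].sum()
        n2 = counts[t + 1 :].sum()
        if n1 == 0 or n2 == 0:
            continue
        w1, w2 = n1 / n, n2 / n
        u1 = (np.arange(t + 1) * counts[: t + 1]).sum() / n1
        u2 = (np.arange(t + 1, 256) * counts[t + 1 :]).sum() / n2
        sigma2[t] = w1 * w2 * (u1 - u2) ** 2
    return int(np.nanargmax(sigma2)), sigma2


# ---------------------------------------------------------------- statistics
def pooled_t_p(x, y):
    """Closed-form pooled-variance two-sample t-test (two-sided)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, df, 2 * stats.t.sf(abs(t), df)


def welch_t_p(x, y):
    """Closed-form Welch t-test with Welch-Satterthwaite df (two-sided)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def levene_p_closed(x, y):
    """Closed-form one-way F on absolute deviations from group means."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    z1, z2 = np.abs(x - x.mean()), np.abs(y - y.mean())
    zs = np.concatenate([z1, z2])
    k, n = 2, len(zs)
    num = (len(z1) * (z1.mean() - zs.mean()) ** 2 + len(z2) * (z2.mean() - zs.mean()) ** 2) / (k - 1)
    den = (((z1 - z1.mean()) ** 2).sum() + ((z2 - z2.mean()) ** 2).sum()) / (n - k)
    F = num / den
    return F, stats.f.sf(F, k - 1, n - k)
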