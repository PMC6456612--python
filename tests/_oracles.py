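"""Independent brute-force oracles used to freeze expected test values."""

from __future__ import annotations

import numpy as np

OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components by explicit stack-based flood fill.

    Returns one frozenset of (row, col) cells per component, in scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                cells = []
                while stack:
                    y, x = stack.pop()
                    cells.append((y, x))
                    for dy, dx in OFFSETS[connectivity]:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(frozenset(cells))
    return comps


def label_map_components(label_map: np.ndarray) -> set[frozenset]:
    """Partition induced by an integer label map (0 = background)."""
    comps = []
    for lbl in np.unique(label_map):
        if lbl == 0:
            continue
        ys, xs = np.where(label_map == lbl)
        comps.append(frozenset(zip(ys.tolist(), xs.tolist())))
    return set(comps)


def otsu_exhaustive(values: np.ndarray) -> float:
    """Otsu threshold by exhaustive search over candidate cuts.

    Maximizes the between-class variance w0*w1*(mu0-mu1)^2 over all splits of
    the sorted unique values; returns the midpoint of the best split.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(vals)
    best, best_t = -1.0, uniq[0]
    for i in range(len(uniq) - 1):
        t = (uniq[i] + uniq[i + 1]) / 2
        lo, hi = vals[vals <= t], vals[vals > t]
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        sb = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sb > best:
            best, best_t = sb, t
    return best_t


def population_threshold(values, eta: float) -> float:
    """mean - eta * population SD, by direct arithmetic."""
    vals = np.asarray(values, dtype=float).ravel()
    mean = vals.sum() / vals.size
    var = ((vals - mean) ** 2).sum() / vals.size
    return mean - eta * np.sqrt(var)


def ols_closed_form(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(X'X)^-1 X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
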