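"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by breadth-first flood fill.

    Deliberately naive (queue + explicit neighbor lists) and independent
    of scipy's labeling, so it can serve as an equivalence oracle.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        raise ValueError(connectivity)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                queue = deque([(r, c)])
                labels[r, c] = current
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and mask[nr, nc] and labels[nr, nc] == 0):
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two labelings agree up to a permutation of label ids."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or np.any((a > 0) != (b > 0)):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len(pairs) == len({p[0] for p in pairs})
            == len({p[1] for p in pairs}))


def gaussian_kernel_2d(sigma: float, radius: int) -> np.ndarray:
    """Directly evaluated, normalized discrete Gaussian kernel."""
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x ** 2) / (2 * sigma ** 2))
    g /= g.sum()
    return np.outer(g, g)


def surviving_component_count(labels: np.ndarray, min_area: int) -> int:
    """Exhaustive enumeration of components with area >= min_area."""
    labels = np.asarray(labels)
    return sum(
        1 for lab in np.unique(labels) if lab != 0
        and int((labels == lab).sum()) >= min_area
    )
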