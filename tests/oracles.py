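"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: flood fill by
explicit queue, surface distances by all-pairs brute force, Wilcoxon by full
sign-pattern enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 26-connected components by explicit queue-based flood fill."""
    mask = mask.astype(bool)
    visited = np.zeros_like(mask)
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not visited[n]:
                    visited[n] = True
                    stack.append(n)
    return count


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask voxels with at least one 6-neighbour outside."""
    mask = mask.astype(bool)
    coords = []
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            n = (z + dz, y + dy, x + dx)
            if not all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                    or not mask[n]:
                coords.append((z, y, x))
                break
    return np.array(coords, dtype=float)


def hd95_bruteforce(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs 95th-percentile symmetric boundary distance in mm."""
    pa = boundary_voxels(a) * np.asarray(spacing)
    pb = boundary_voxels(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    forward = np.percentile(d.min(axis=1), 95)
    backward = np.percentile(d.min(axis=0), 95)
    return float(max(forward, backward))


def dsc_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    inter = sum(1 for idx in zip(*np.nonzero(a)) if b[idx])
    sa, sb = int(a.sum()), int(b.sum())
    return 1.0 if sa + sb == 0 else 2.0 * inter / (sa + sb)


def wilcoxon_exact_enumeration(diff: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Zero differences are dropped; assumes no ties among |differences|.
    Matches the convention p = min(1, 2 * min(P(T+ <= t), P(T+ >= t))).
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    t_obs = ranks[d > 0].sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([False, True], repeat=n)]
    stats = np.array(stats)
    p_low = np.mean(stats <= t_obs)
    p_high = np.mean(stats >= t_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
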