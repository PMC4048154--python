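"""Independent brute-force oracles used by the test suite.

Everything here is deliberately slow and literal: breadth-first flood fill
for connected components, per-element loops for correlations and t-values,
and a straight-line re-implementation of one permutation pass.  None of it
shares code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def face_edge_neighbors(coord, shape):
    """Neighbours sharing a face or an edge (never only a corner)."""
    coord = tuple(coord)
    ndim = len(shape)
    out = []
    for offset in np.ndindex(*(3,) * ndim):
        delta = np.array(offset) - 1
        n_moved = int(np.count_nonzero(delta))
        if n_moved == 0:
            continue
        if ndim == 3 and n_moved == 3:  # corner-only contact in 3-D
            continue
        nb = tuple(np.array(coord) + delta)
        if all(0 <= nb[d] < shape[d] for d in range(ndim)):
            out.append(nb)
    return out


def bfs_clusters(binary: np.ndarray) -> list[set]:
    """Connected components of a binary image by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for nb in face_edge_neighbors(cur, binary.shape):
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(comp)
    return comps


def pearson_loop(x: np.ndarray) -> np.ndarray:
    """Definitional per-pair Pearson correlation."""
    n = x.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            r = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            out[i, j] = out[j, i] = r
    return out


def paired_t_scalar(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook paired t for one element across subjects."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(n)))


def signflip_pvalue_scalar(a: np.ndarray, b: np.ndarray) -> float:
    """Full-enumeration sign-flip permutation p for one paired sample.

    One-sided (>=) p of the observed t among all 2^n sign-flipped t values.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t_obs = paired_t_scalar(a, b)
    count = 0
    for code in range(2**n):
        signs = np.array([1 if (code >> i) & 1 == 0 else -1
                          for i in range(n)])
        dd = d * signs
        t = dd.mean() / (dd.std(ddof=1) / np.sqrt(n))
        if t >= t_obs:
            count += 1
    return count / 2**n


def max_cluster_stats_straightline(mats_A, mats_B, flips, t0, mask):
    """Independent recomputation of one permutation's max CSS and CMS.

    Loops over matrix elements for the t-values, thresholds, counts links
    per voxel, and floods clusters with the BFS oracle.
    """
    A = np.asarray(mats_A, float)
    B = np.asarray(mats_B, float)
    n, N, _ = A.shape
    coords = [tuple(c) for c in np.argwhere(mask)]
    counts = np.zeros(N, dtype=int)
    for i in range(N):
        for j in range(i + 1, N):
            diffs = np.array([flips[s] * (A[s, i, j] - B[s, i, j])
                              for s in range(n)])
            sd = diffs.std(ddof=1)
            t = 0.0 if sd == 0 else diffs.mean() / (sd / np.sqrt(n))
            if t > t0:
                counts[i] += 1
                counts[j] += 1
    binary = np.zeros(mask.shape, dtype=bool)
    count_img = np.zeros(mask.shape, dtype=int)
    for v, c in enumerate(coords):
        binary[c] = counts[v] > 0
        count_img[c] = counts[v]
    comps = bfs_clusters(binary)
    if not comps:
        return 0, 0
    css = max(len(c) for c in comps)
    cms = max(sum(count_img[v] for v in c) for c in comps)
    return css, cms


def critical_size_scan(values, alpha):
    """Smallest s with count(values >= s)/P <= alpha, by linear scan."""
    values = np.asarray(values)
    P = values.size
    s = 0
    while np.count_nonzero(values >= s) / P > alpha:
        s += 1
    return max(s, 1)
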