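"""Independent brute-force oracles used by the test suite.

These deliberately do not share code with the package: the sublevel oracle
is a plain union-find over samples, the Rips oracle is a full boundary-matrix
reduction over all simplices, and the Spearman oracle computes mid-ranks by
sorting.  They are only feasible at tiny sizes, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np


def sublevel_pairs_bruteforce(series) -> list[tuple[float, float]]:
    """0-dim sublevel persistence by explicit union-find over all samples."""
    x = np.asarray(series, dtype=float)
    n = x.size
    order = sorted(range(n), key=lambda i: (x[i], i))
    parent = {}
    birth = {}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = []
    rank = {idx: r for r, idx in enumerate(order)}
    for i in order:
        parent[i] = i
        birth[i] = x[i]
        for j in (i - 1, i + 1):
            if j in parent:
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                if (birth[ri], rank[ri]) > (birth[rj], rank[rj]):
                    young, old = ri, rj
                else:
                    young, old = rj, ri
                if birth[young] < x[i]:
                    pairs.append((birth[young], x[i]))
                parent[young] = old
    return sorted(pairs)


def rips_pairs_bruteforce(points, max_dim: int = 1):
    """Vietoris-Rips persistence by full boundary-matrix reduction.

    Builds every simplex up to dimension max_dim + 1, orders by (filtration
    value, dimension, vertex tuple), and runs the standard column reduction
    over Z2.  Returns (finite_pairs, essential) where finite_pairs is a
    sorted list of (birth, death, dim) with death > birth and essential a
    sorted list of (birth, dim).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))

    simplices = []
    for d in range(max_dim + 2):
        for verts in itertools.combinations(range(n), d + 1):
            if d == 0:
                f = 0.0
            else:
                f = max(dist[a][b] for a, b in itertools.combinations(verts, 2))
            simplices.append((f, d, verts))
    simplices.sort()
    index_of = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for f, d, verts in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append(
                {index_of[face] for face in itertools.combinations(verts, d)}
            )

    low_to_col = {}
    pair_of = {}
    for j, col in enumerate(columns):
        col = set(col)
        while col:
            low = max(col)
            if low in low_to_col:
                col ^= columns[low_to_col[low]]
            else:
                low_to_col[low] = j
                columns[j] = col
                pair_of[low] = j
                break

    finite, essential = [], []
    paired_deaths = set(pair_of.values())
    for i, (f, d, verts) in enumerate(simplices):
        if i in pair_of:
            j = pair_of[i]
            fb, fd = f, simplices[j][0]
            if fd > fb and d <= max_dim:
                finite.append((fb, fd, d))
        elif i not in paired_deaths and d <= max_dim:
            essential.append((f, d))
    return sorted(finite), sorted(essential)


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of mid-ranks, ranks computed by explicit sorting."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def epoch_count_bruteforce(duration_s: float, window_s: float, step_s: float) -> int:
    """Count epochs by explicit enumeration."""
    count = 0
    start = 0.0
    while start + window_s <= duration_s:
        count += 1
        start += step_s
    return count
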