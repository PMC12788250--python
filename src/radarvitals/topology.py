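"""Persistence-homology primitives for periodicity detection in 1-D series.

Two filtrations are used.  The sublevel-set filtration of a series tracks
connected components of ``{t : x(t) <= h}`` as the level ``h`` rises: each
strict local minimum births a component, and components merge at local
maxima, the younger dying (elder rule).  A periodic signal of amplitude ``a``
therefore produces one long-persistence 0-dim pair per oscillation cycle,
with persistence close to the peak-to-peak amplitude ``2a``.

The Vietoris-Rips filtration of a delay-embedded window detects the loop a
periodic signal traces in embedding space: a clean oscillation yields a
single dominant 1-dimensional class whose death/birth ratio is large, while
aperiodic noise embeds as a blob with ratio near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters: point i = (x_i, x_{i+lag}, ...)."""

    dimension: int = 2
    lag_samples: int = 20

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.lag_samples < 1:
            raise ValueError("lag_samples must be >= 1")


@dataclass
class PersistenceDiagram:
    """Finite (birth, death, dim) pairs plus essential (birth, dim) classes."""

    pairs: np.ndarray  # shape (n, 3): birth, death, dim
    essential: np.ndarray  # shape (m, 2): birth, dim

    def __post_init__(self) -> None:
        self.pairs = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        if self.pairs.size == 0:
            self.pairs = np.empty((0, 3))
        self.essential = np.atleast_2d(np.asarray(self.essential, dtype=float))
        if self.essential.size == 0:
            self.essential = np.empty((0, 2))

    def in_dim(self, dim: int) -> np.ndarray:
        """Finite (birth, death) pairs of one homology dimension."""
        sel = self.pairs[self.pairs[:, 2] == dim]
        return sel[:, :2]

    def persistences(self, dim: int) -> np.ndarray:
        bd = self.in_dim(dim)
        return bd[:, 1] - bd[:, 0]

    def to_array(self) -> np.ndarray:
        return self.pairs.copy()


def sublevel_diagram(series: np.ndarray) -> PersistenceDiagram:
    """0-dim persistence of the sublevel-set filtration of a 1-D series.

    Values are processed in increasing order; a component born at a strict
    local minimum dies when merged into a component with an older (lower)
    birth.  Plateaus are tie-broken by index (earlier index is older), so the
    result is deterministic.  The global minimum yields the single essential
    class.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("series must have length >= 1")
    x = _extrema_compress(x)
    n = x.size

    order = np.lexsort((np.arange(n), x))  # by value, then index
    parent = np.full(n, -1, dtype=np.int64)  # union-find; -1 = not yet alive
    birth = np.empty(n)
    pairs: list[tuple[float, float]] = []

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    rank_of = np.empty(n, dtype=np.int64)
    rank_of[order] = np.arange(n)

    for i in order:
        parent[i] = i
        birth[i] = x[i]
        for j in (i - 1, i + 1):
            if 0 <= j < n and parent[j] != -1:
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                # elder rule: the component with the younger birth dies here
                bi, bj = birth[ri], birth[rj]
                # tie-break births by the filtration rank of the root index
                younger, elder = (ri, rj) if (bi, rank_of[ri]) > (bj, rank_of[rj]) else (rj, ri)
                if birth[younger] < x[i]:
                    pairs.append((birth[younger], x[i]))
                parent[younger] = elder
    essential = np.array([[x.min(), 0.0]])
    arr = (
        np.array([[b, d, 0.0] for b, d in pairs])
        if pairs
        else np.empty((0, 3))
    )
    return PersistenceDiagram(arr, essential)


def _extrema_compress(x: np.ndarray) -> np.ndarray:
    """Drop interior points of monotone runs and plateaus.

    The sublevel 0-dim diagram depends only on the sequence of local
    extremum values, so compressing first makes the union-find near-linear
    in the number of oscillations instead of samples.  Plateau merges would
    only produce zero-persistence pairs, which the diagram drops anyway.
    """
    if x.size <= 2:
        return x
    keep = np.concatenate([[True], np.diff(x) != 0])
    x = x[keep]
    if x.size <= 2:
        return x
    s = np.sign(np.diff(x))
    turning = s[:-1] != s[1:]
    mask = np.concatenate([[True], turning, [True]])
    return x[mask]


def delay_embed(series: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    """Takens delay embedding of a series into R^dimension.

    Point ``i`` is ``(x_i, x_{i+lag}, ..., x_{i+(d-1)lag})``; the output has
    ``len(series) - (d-1)*lag`` points.
    """
    x = np.asarray(series, dtype=float).ravel()
    span = (cfg.dimension - 1) * cfg.lag_samples
    n_points = x.size - span
    if n_points < 1:
        raise ValueError(
            f"series of length {x.size} too short for dimension "
            f"{cfg.dimension}, lag {cfg.lag_samples}"
        )
    cols = [x[k * cfg.lag_samples : k * cfg.lag_samples + n_points]
            for k in range(cfg.dimension)]
    return np.column_stack(cols)


@njit(cache=False)
def _reduce_triangles(tri_edges, tri_filt, edge_filt, n_edges):  # pragma: no cover
    """Z2 column reduction of the triangle boundary matrix (H1 pairs).

    Edges are indexed by filtration rank so the column pivot is the highest
    set bit.  Columns are uint64 bitsets.  Returns (births, deaths, count)
    for pairs with death > birth.
    """
    words = (n_edges + 63) >> 6
    cols = np.zeros((n_edges, words), dtype=np.uint64)
    has_pivot = np.zeros(n_edges, dtype=np.bool_)
    births = np.empty(n_edges)
    deaths = np.empty(n_edges)
    n_pairs = 0
    work = np.zeros(words, dtype=np.uint64)
    m = tri_edges.shape[0]
    for t in range(m):
        for w in range(words):
            work[w] = np.uint64(0)
        for k in range(3):
            e = tri_edges[t, k]
            work[e >> 6] ^= np.uint64(1) << np.uint64(e & 63)
        while True:
            # locate the pivot (highest set bit)
            pivot = -1
            for w in range(words - 1, -1, -1):
                if work[w] != np.uint64(0):
                    b = work[w]
                    pos = 0
                    while b > np.uint64(1):
                        b >>= np.uint64(1)
                        pos += 1
                    pivot = (w << 6) + pos
                    break
            if pivot < 0:
                break  # column reduced to zero: births a 2-cycle, ignored
            if has_pivot[pivot]:
                for w in range(words):
                    work[w] ^= cols[pivot, w]
            else:
                for w in range(words):
                    cols[pivot, w] = work[w]
                has_pivot[pivot] = True
                if tri_filt[t] > edge_filt[pivot]:
                    births[n_pairs] = edge_filt[pivot]
                    deaths[n_pairs] = tri_filt[t]
                    n_pairs += 1
                break
    return births, deaths, n_pairs


def _rips_h0(dist: np.ndarray) -> np.ndarray:
    """0-dim Rips pairs via the minimum spanning tree: (0, merge distance)."""
    from scipy.sparse.csgraph import minimum_spanning_tree

    mst = minimum_spanning_tree(dist)
    deaths = np.sort(mst.data)
    out = np.zeros((deaths.size, 3))
    out[:, 1] = deaths
    return out


def rips_diagram(
    points: np.ndarray, max_dim: int = 1, max_points: int = 200
) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a Euclidean point cloud up to dim 1.

    An edge enters the filtration at the pairwise distance of its endpoints;
    higher simplices at their longest edge.  Clouds larger than
    ``max_points`` are uniformly decimated first (the large-scale loop
    topology of a densely sampled closed curve survives decimation).

    0-dim pairs come from the minimum spanning tree; 1-dim pairs from Z2
    reduction of the triangle boundary matrix.  Zero-persistence pairs are
    dropped.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] > max_points:
        idx = np.linspace(0, pts.shape[0] - 1, max_points).round().astype(int)
        pts = pts[np.unique(idx)]
    n = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))

    parts = [_rips_h0(dist)]
    essential = np.array([[0.0, 0.0]])

    if max_dim >= 1 and n >= 3:
        iu, ju = np.triu_indices(n, k=1)
        edge_d = dist[iu, ju]
        order = np.lexsort((ju, iu, edge_d))  # filtration order, deterministic ties
        edge_filt = edge_d[order]
        rank = np.empty(edge_d.size, dtype=np.int64)
        rank[order] = np.arange(edge_d.size)
        edge_rank = np.zeros((n, n), dtype=np.int64)
        edge_rank[iu, ju] = rank
        edge_rank[ju, iu] = rank

        ti, tj, tk = _triangle_indices(n)
        e1 = edge_rank[ti, tj]
        e2 = edge_rank[ti, tk]
        e3 = edge_rank[tj, tk]
        tri_edges = np.column_stack([e1, e2, e3]).astype(np.int64)
        tri_rank = tri_edges.max(axis=1)
        tri_filt = edge_filt[tri_rank]
        t_order = np.lexsort((e3, e2, e1, tri_rank))
        births, deaths, n_pairs = _reduce_triangles(
            tri_edges[t_order], tri_filt[t_order], edge_filt, edge_filt.size
        )
        if n_pairs:
            h1 = np.column_stack(
                [births[:n_pairs], deaths[:n_pairs], np.ones(n_pairs)]
            )
            parts.append(h1)
    pairs = np.vstack(parts) if parts else np.empty((0, 3))
    pairs = pairs[pairs[:, 1] > pairs[:, 0]]
    return PersistenceDiagram(pairs, essential)


def _triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All i<j<k triples for n points, vectorized."""
    r = np.arange(n, dtype=np.int32)
    i, j, k = np.meshgrid(r, r, r, indexing="ij", sparse=False, copy=False)
    mask = (i < j) & (j < k)
    return i[mask], j[mask], k[mask]


def periodicity_scores(
    d0: PersistenceDiagram, d1: PersistenceDiagram | None = None, tau: float = 0.0
) -> dict[str, float]:
    """Summary scores of a window's persistence diagrams.

    Returns ``max_persistence_0``, ``persistence_count_0`` (finite 0-dim
    pairs with persistence >= tau), ``max_persistence_1`` and
    ``persistence_ratio_1`` (death/birth of the most persistent 1-dim pair;
    0 when there is none).
    """
    p0 = d0.persistences(0) if d0 is not None else np.empty(0)
    scores = {
        "max_persistence_0": float(p0.max()) if p0.size else 0.0,
        "persistence_count_0": int((p0 >= tau).sum()) if p0.size else 0,
        "max_persistence_1": 0.0,
        "persistence_ratio_1": 0.0,
    }
    if d1 is not None:
        bd1 = d1.in_dim(1)
        if bd1.shape[0]:
            p1 = bd1[:, 1] - bd1[:, 0]
            best = int(np.argmax(p1))
            scores["max_persistence_1"] = float(p1[best])
            birth = bd1[best, 0]
            scores["persistence_ratio_1"] = (
                float(bd1[best, 1] / birth) if birth > 0 else float("inf")
            )
    return scores


def diagram_to_csv(diagram: PersistenceDiagram, path) -> None:
    """Serialize finite pairs to CSV columns (birth, death, dim)."""
    np.savetxt(
        path,
        diagram.pairs,
        delimiter=",",
        header="birth,death,dim",
        comments="",
        fmt="%.12g",
    )
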