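"""Persistent homology of embedded trajectories.

A trajectory is a point cloud E in low-dimensional space.  Its shape is
summarized by the Vietoris-Rips filtration: points within distance eps of
each other are connected, eps grows from 0 until everything is one clique,
and the births/deaths of connected components (H0), loops (H1) and voids
(H2) along the way form the persistence diagram.  Smooth signalling
trajectories produce a few large loops born late; disordered point-cloud
trajectories produce many small loops born and dying early.

Diagrams are compared with the 2-Wasserstein distance: the minimum quadratic
transport cost of matching the bars of one diagram to the other, with
unmatched bars sent to their orthogonal projection on the diagonal.  The
matching is solved exactly as an assignment problem.

Implementation notes: H0 comes from union-find over the sorted edges.  H1/H2
come from GF(2) boundary-matrix reduction restricted to one dimension at a
time (a column's pivot row is always a creator simplex of the dimension
below, so the dimensions decouple), with columns as bitsets in a
numba-compiled kernel; this is exact, not approximate.  The single infinite
H0 bar is capped at the maximum pairwise distance and flagged, so diagram
distances stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PersistenceDiagram",
    "BettiCurve",
    "rips_persistence",
    "betti_curve",
    "wasserstein",
    "wasserstein_matrix",
]


@dataclass
class PersistenceDiagram:
    """Bars (birth, death, dimension) of a filtration, with capped infinities.

    ``capped`` marks bars whose true death is infinite; their stored death is
    ``cap`` (the max pairwise distance under the auto convention).
    """

    births: np.ndarray
    deaths: np.ndarray
    dims: np.ndarray
    capped: np.ndarray
    cap: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.dims = np.asarray(self.dims, dtype=int)
        self.capped = np.asarray(self.capped, dtype=bool)
        if not (self.births.shape == self.deaths.shape == self.dims.shape == self.capped.shape):
            raise ValueError("bar fields must have equal length")
        if np.any(self.births < 0):
            raise ValueError("births must be nonnegative")
        if np.any(self.deaths < self.births):
            raise ValueError("every bar needs birth <= death")

    @property
    def n_bars(self) -> int:
        return self.births.shape[0]

    def bars_of(self, dimension: int) -> np.ndarray:
        """(k, 2) array of (birth, death) for one homology dimension."""
        sel = self.dims == dimension
        return np.stack([self.births[sel], self.deaths[sel]], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimension": self.dims,
                "birth": self.births,
                "death": self.deaths,
                "capped": self.capped.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PersistenceDiagram":
        df = pd.read_csv(path)
        deaths = df["death"].to_numpy(dtype=float)
        cap = float(deaths.max()) if len(deaths) else 0.0
        return cls(
            births=df["birth"].to_numpy(dtype=float),
            deaths=deaths,
            dims=df["dimension"].to_numpy(dtype=int),
            capped=df["capped"].to_numpy(dtype=bool),
            cap=cap,
            metadata={"source": str(path)},
        )


@dataclass
class BettiCurve:
    """Feature count of one homology dimension along a threshold grid."""

    thresholds: np.ndarray
    counts: np.ndarray
    dimension: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "count": self.counts})


# ---------------------------------------------------------------------------
# boundary-matrix reduction (GF(2), bitset columns)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _enumerate_triangles(m):  # pragma: no cover - exercised via rips_persistence
    count = m * (m - 1) * (m - 2) // 6
    out = np.empty((count, 3), np.int64)
    q = 0
    for i in range(m):
        for j in range(i + 1, m):
            for k in range(j + 1, m):
                out[q, 0] = i
                out[q, 1] = j
                out[q, 2] = k
                q += 1
    return out


@njit(cache=True)
def _reduce_columns(cols, n_rows):  # pragma: no cover - exercised via rips_persistence
    """Standard persistence column reduction over GF(2).

    ``cols``: (n_cols, f) face row-indices per column, columns already in
    filtration order; rows are the (dim-1)-simplices in filtration order.
    Returns ``low_of_col`` (pivot row of each column, -1 if the column
    reduced to zero) -- pivots are exactly the persistence pairs.
    """
    n_cols, f = cols.shape
    W = (n_rows + 63) >> 6
    pair_col_of_row = np.full(n_rows, -1, np.int64)
    stored = np.zeros((n_rows, W), np.uint64)  # reduced column keyed by its pivot
    low_of_col = np.full(n_cols, -1, np.int64)
    cur = np.zeros(W, np.uint64)
    one = np.uint64(1)
    for c in range(n_cols):
        top_word = 0
        for w in range(W):
            cur[w] = np.uint64(0)
        for q in range(f):
            r = cols[c, q]
            w = r >> 6
            cur[w] ^= one << np.uint64(r & 63)
            if w > top_word:
                top_word = w
        while True:
            low = -1
            for w in range(top_word, -1, -1):
                v = cur[w]
                if v != np.uint64(0):
                    b = 0
                    while v > one:
                        v >>= one
                        b += 1
                    low = (w << 6) + b
                    top_word = w
                    break
            if low < 0:
                break
            other = pair_col_of_row[low]
            if other < 0:
                pair_col_of_row[low] = c
                low_of_col[c] = low
                for w in range(top_word + 1):
                    stored[low, w] = cur[w]
                break
            for w in range(top_word + 1):
                cur[w] ^= stored[low, w]
    return low_of_col


def _h0_union_find(m: int, edges_sorted: np.ndarray, lengths_sorted: np.ndarray):
    """H0 bars and the merge status of every edge, by Kruskal union-find."""
    parent = np.arange(m)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    deaths: List[float] = []
    merges = np.zeros(len(edges_sorted), dtype=bool)
    for e, (i, j) in enumerate(edges_sorted):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
            deaths.append(float(lengths_sorted[e]))
            merges[e] = True
    n_components = m - len(deaths)
    return deaths, merges, n_components


def rips_persistence(
    points: np.ndarray,
    max_dim: int = 1,
    max_filtration: Union[str, float] = "auto",
) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a Euclidean point cloud.

    Parameters
    ----------
    points : (m, d) array
        Embedded trajectory (or any point cloud).  A 1D array is treated as
        points on a line.
    max_dim : int
        Highest homology dimension, 0..2.  H2 enumerates all 3-simplices and
        is intended for small (desk-scale) point sets.
    max_filtration : "auto" or float
        Filtration ceiling; "auto" runs to the maximum pairwise distance so
        the complex ends fully connected.  Features still alive at the
        ceiling are capped there and flagged.

    Zero-persistence bars (death equal to birth) are dropped.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("points must be a nonempty (m, d) array")
    if not np.isfinite(P).all():
        raise ValueError("points must be finite")
    if not 0 <= max_dim <= 2:
        raise ValueError("max_dim must be 0, 1, or 2")
    m = P.shape[0]

    births: List[float] = []
    deaths: List[float] = []
    dims: List[int] = []
    capped: List[bool] = []

    if m == 1:
        return PersistenceDiagram(
            births=np.array([0.0]), deaths=np.array([0.0]), dims=np.array([0]),
            capped=np.array([True]), cap=0.0, metadata={"n_points": 1},
        )

    D = squareform(pdist(P))
    cap = float(D.max()) if max_filtration == "auto" else float(max_filtration)

    ii, jj = np.triu_indices(m, 1)
    lengths = D[ii, jj]
    keep = lengths <= cap
    ii, jj, lengths = ii[keep], jj[keep], lengths[keep]
    order = np.lexsort((jj, ii, lengths))
    edges = np.stack([ii[order], jj[order]], axis=1)
    elen = lengths[order]

    h0_deaths, merges, n_components = _h0_union_find(m, edges, elen)
    for d in h0_deaths:
        if d > 0.0:
            births.append(0.0)
            deaths.append(d)
            dims.append(0)
            capped.append(False)
    for _ in range(n_components):
        births.append(0.0)
        deaths.append(cap)
        dims.append(0)
        capped.append(True)

    tri_creators = np.empty((0,), dtype=np.int64)
    tri_filt_kept = np.empty((0,))
    tri_keys: List[tuple] = []
    if max_dim >= 1 and m >= 2:
        n_edges = len(edges)
        rank2d = np.full((m, m), -1, dtype=np.int64)
        rank2d[edges[:, 0], edges[:, 1]] = np.arange(n_edges)
        rank2d[edges[:, 1], edges[:, 0]] = np.arange(n_edges)
        if m >= 3:
            tri = _enumerate_triangles(m)
            tf = np.maximum(
                np.maximum(D[tri[:, 0], tri[:, 1]], D[tri[:, 0], tri[:, 2]]),
                D[tri[:, 1], tri[:, 2]],
            )
            sel = tf <= cap
            tri, tf = tri[sel], tf[sel]
            t_order = np.argsort(tf, kind="stable")
            tri, tf = tri[t_order], tf[t_order]
            faces = np.stack(
                [
                    rank2d[tri[:, 0], tri[:, 1]],
                    rank2d[tri[:, 0], tri[:, 2]],
                    rank2d[tri[:, 1], tri[:, 2]],
                ],
                axis=1,
            )
            low = _reduce_columns(faces, n_edges) if len(faces) else np.empty(0, np.int64)
            paired_edge = {}
            for c, lw in enumerate(low):
                if lw >= 0:
                    paired_edge[int(lw)] = float(tf[c])
            # H1 creators: edges that closed a cycle (did not merge components)
            for e in np.nonzero(~merges)[0]:
                birth = float(elen[e])
                if int(e) in paired_edge:
                    death = paired_edge[int(e)]
                    if death > birth:
                        births.append(birth)
                        deaths.append(death)
                        dims.append(1)
                        capped.append(False)
                elif cap > birth:
                    births.append(birth)
                    deaths.append(cap)
                    dims.append(1)
                    capped.append(True)
            tri_creators = np.nonzero(low == -1)[0] if len(faces) else np.empty(0, np.int64)
            tri_filt_kept = tf
            tri_keys = [tuple(t) for t in tri.tolist()]
        else:
            tri_keys = []

    if max_dim >= 2 and m >= 4:
        tri_rank = {key: r for r, key in enumerate(tri_keys)}
        tets = []
        tet_filt = []
        for quad in combinations(range(m), 4):
            sub = D[np.ix_(quad, quad)]
            f = float(sub.max())
            if f <= cap:
                tets.append(quad)
                tet_filt.append(f)
        if tets:
            tet_filt = np.asarray(tet_filt)
            t_order = np.argsort(tet_filt, kind="stable")
            tet_filt = tet_filt[t_order]
            faces4 = np.empty((len(tets), 4), dtype=np.int64)
            for row, oi in enumerate(t_order):
                quad = tets[oi]
                for fi, face in enumerate(combinations(quad, 3)):
                    faces4[row, fi] = tri_rank[face]
            low2 = _reduce_columns(faces4, len(tri_keys))
            paired_tri = {}
            for c, lw in enumerate(low2):
                if lw >= 0:
                    paired_tri[int(lw)] = float(tet_filt[c])
            for tr in tri_creators:
                birth = float(tri_filt_kept[tr])
                if int(tr) in paired_tri:
                    death = paired_tri[int(tr)]
                    if death > birth:
                        births.append(birth)
                        deaths.append(death)
                        dims.append(2)
                        capped.append(False)
                elif cap > birth:
                    births.append(birth)
                    deaths.append(cap)
                    dims.append(2)
                    capped.append(True)

    return PersistenceDiagram(
        births=np.asarray(births), deaths=np.asarray(deaths),
        dims=np.asarray(dims, dtype=int), capped=np.asarray(capped, dtype=bool),
        cap=cap, metadata={"n_points": m, "max_dim": max_dim},
    )


def betti_curve(
    diagram: PersistenceDiagram,
    dimension: int,
    thresholds: Optional[np.ndarray] = None,
) -> BettiCurve:
    """beta_q(eps) = number of dimension-q bars alive at eps (birth <= eps < death).

    Capped bars never die for the purposes of the curve (their true death is
    infinite).  Default grid: 100 even thresholds from 0 to the diagram cap.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, diagram.cap if diagram.cap > 0 else 1.0, 100)
    thresholds = np.asarray(thresholds, dtype=float)
    sel = diagram.dims == dimension
    births = diagram.births[sel]
    deaths = np.where(diagram.capped[sel], np.inf, diagram.deaths[sel])
    counts = (
        (births[None, :] <= thresholds[:, None]) & (thresholds[:, None] < deaths[None, :])
    ).sum(axis=1)
    return BettiCurve(thresholds=thresholds, counts=counts.astype(int), dimension=dimension)


def wasserstein(
    Q1: PersistenceDiagram,
    Q2: PersistenceDiagram,
    dimension: int = 0,
    exponent: int = 2,
) -> float:
    """Exact 2-Wasserstein distance between two diagrams in one dimension.

    Bars of each diagram may be matched to bars of the other or to their
    orthogonal projection on the diagonal; the optimal matching minimizes the
    sum of squared Euclidean distances and the returned value is the square
    root of that minimum.  Solved exactly on the diagonally-augmented cost
    matrix with the Hungarian algorithm.
    """
    if exponent != 2:
        raise ValueError("only the 2-Wasserstein distance is supported")
    a = Q1.bars_of(dimension)
    b = Q2.bars_of(dimension)
    n1, n2 = len(a), len(b)
    if n1 == 0 and n2 == 0:
        return 0.0
    big = 1e18
    size = n1 + n2
    C = np.zeros((size, size))
    if n1 and n2:
        diff = a[:, None, :] - b[None, :, :]
        C[:n1, :n2] = (diff**2).sum(-1)
    diag_a = 0.5 * (a[:, 1] - a[:, 0]) ** 2  # squared distance to the diagonal
    diag_b = 0.5 * (b[:, 1] - b[:, 0]) ** 2
    C[:n1, n2:] = big
    C[n1:, :n2] = big
    C[np.arange(n1), n2 + np.arange(n1)] = diag_a
    C[n1 + np.arange(n2), np.arange(n2)] = diag_b
    rows, cols = linear_sum_assignment(C)
    return float(np.sqrt(C[rows, cols].sum()))


def wasserstein_matrix(
    diagrams: Sequence[PersistenceDiagram],
    dimension: int = 0,
    ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Square table of pairwise diagram distances (replicate comparisons)."""
    n = len(diagrams)
    ids = list(ids) if ids is not None else list(range(n))
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = wasserstein(diagrams[i], diagrams[j], dimension)
    return pd.DataFrame(M, index=ids, columns=ids)
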