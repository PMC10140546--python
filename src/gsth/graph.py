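"""Cellular graphs: the spatial substrate Ca2+ signals live on.

A recording is modelled as a graph G = (V, E) with one vertex per cell and
an edge between cells that can plausibly exchange signal.  Three builders are
provided, matching the three kinds of raw input that occur in practice:

* a segmentation label mask (epithelial sheets) -- edges from region contact,
* explicit 2D centroids (when only positions survive) -- kNN or radius rule,
* the signal matrix itself (neurons with long processes, where physical
  adjacency is meaningless) -- edges from trace correlation.

The graph is undirected and unweighted: ``adjacency`` is a symmetric 0/1
matrix with zero diagonal, and ``degrees`` its row sums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellGraph",
    "build_graph_from_labels",
    "build_graph_from_positions",
    "build_graph_from_correlation",
    "read_label_mask",
    "read_positions_csv",
    "save_graph",
    "load_graph",
]


@dataclass
class CellGraph:
    """An undirected cellular graph.

    Parameters
    ----------
    adjacency : (n, n) ndarray
        Symmetric 0/1 matrix with zero diagonal.
    cell_ids : sequence of length n
        Stable identifiers mapping matrix rows to cells (mask labels, CSV ids,
        or plain integers).  Must be unique.
    positions : (n, 2) ndarray, optional
        Cell coordinates in pixels or microns; absent for correlation graphs.
    meta : dict
        Builder provenance (builder name and parameters), serialized alongside
        any export.
    """

    adjacency: np.ndarray
    cell_ids: np.ndarray
    positions: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A.astype(np.float64)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.cell_ids.shape[0] != A.shape[0]:
            raise ValueError("cell_ids length must match adjacency size")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (A.shape[0], 2):
                raise ValueError("positions must be n x 2")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Vertex degrees D_ii = sum_j A_ij."""
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """Edges as an (E, 2) array of cell_id pairs, source index < target."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.stack([self.cell_ids[i], self.cell_ids[j]], axis=1)

    def index_of(self, cell_id) -> int:
        hits = np.nonzero(self.cell_ids == cell_id)[0]
        if len(hits) == 0:
            raise KeyError(f"unknown cell_id {cell_id!r}")
        return int(hits[0])


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_graph_from_labels(
    label_mask: np.ndarray, background_value: int = 0, gap: int = 1
) -> CellGraph:
    """Build a region-contact graph from an integer segmentation mask.

    Two labelled regions are connected when they have at least one pair of
    pixels within city-block distance ``gap`` of each other (``gap=1`` means
    the regions share a border; larger gaps tolerate hairline segmentation
    gaps).  Regions that touch only at a corner are not adjacent, matching
    the contact graph of a tiling of squares.
    Positions are set to the unweighted centroid of each region's pixels,
    in 0-based ``(x, y) = (col, row)`` pixel coordinates.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be integer-valued")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    labels = np.unique(mask)
    labels = labels[labels != background_value]
    if labels.size == 0:
        raise ValueError("mask contains no non-background labels")
    if labels.min() < 0:
        raise ValueError("labels must be positive integers")

    n = labels.size
    pos_of = {int(lab): k for k, lab in enumerate(labels)}
    A = np.zeros((n, n))

    # Pairs of distinct labels within city-block distance <= gap: compare the
    # mask with all of its shifts by (dy, dx), |dy| + |dx| <= gap.
    h, w = mask.shape
    for dy in range(-gap, gap + 1):
        for dx in range(0, gap + 1 - abs(dy)):
            if dx == 0 and dy <= 0:
                continue  # half-plane of offsets suffices (symmetry)
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            ys0 = slice(max(0, -dy), min(h, h - dy))
            xs0 = slice(max(0, -dx), min(w, w - dx))
            a = mask[ys0, xs0]
            b = mask[ys, xs]
            sel = (a != b) & (a != background_value) & (b != background_value)
            if not sel.any():
                continue
            pairs = np.unique(
                np.stack([a[sel], b[sel]], axis=1), axis=0
            )
            for la, lb in pairs:
                ia, ib = pos_of[int(la)], pos_of[int(lb)]
                A[ia, ib] = A[ib, ia] = 1.0

    centroids = np.zeros((n, 2))
    rows, cols = np.nonzero(mask != background_value)
    vals = mask[rows, cols]
    for k, lab in enumerate(labels):
        sel = vals == lab
        centroids[k] = [cols[sel].mean(), rows[sel].mean()]

    return CellGraph(
        adjacency=A,
        cell_ids=labels,
        positions=centroids,
        meta={"builder": "labels", "gap": gap, "background": int(background_value)},
    )


def build_graph_from_positions(
    positions: np.ndarray,
    mode: str = "knn",
    param: float = 5,
    cell_ids: Optional[Sequence] = None,
) -> CellGraph:
    """Build a proximity graph from 2D cell positions.

    ``mode='knn'`` connects each point to its ``param`` nearest neighbours
    (ties broken by smaller index) and symmetrizes by union; ``mode='radius'``
    connects pairs with Euclidean distance <= ``param``.
    """
    P = np.asarray(positions, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("positions must be n x 2")
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 positions")
    if param <= 0:
        raise ValueError("param must be positive")
    D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    A = np.zeros((n, n))
    if mode == "knn":
        k = int(param)
        idx = np.arange(n)
        for i in range(n):
            order = np.lexsort((idx, D[i]))
            order = order[order != i][:k]
            A[i, order] = 1.0
        A = np.maximum(A, A.T)  # symmetrized union
    elif mode == "radius":
        A = (D <= param).astype(float)
        np.fill_diagonal(A, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ids = np.arange(n) if cell_ids is None else np.asarray(cell_ids)
    return CellGraph(
        adjacency=A, cell_ids=ids, positions=P,
        meta={"builder": "positions", "mode": mode, "param": param},
    )


def build_graph_from_correlation(signals, threshold: float) -> CellGraph:
    """Build a graph by thresholding pairwise Pearson correlation of traces.

    Intended for neuron-style recordings where spatial adjacency does not
    reflect connectivity.  ``signals`` is a SignalMatrix or an (n, T) array.
    An edge is placed where r >= threshold.  No positions are attached.
    """
    values = np.asarray(getattr(signals, "values", signals), dtype=float)
    cell_ids = getattr(signals, "cell_ids", None)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need an (n >= 2) x T signal matrix")
    if not (-1.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (-1, 1]")
    sd = values.std(axis=1)
    ids = np.arange(values.shape[0]) if cell_ids is None else np.asarray(cell_ids)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"constant trace for cell(s) {ids[bad].tolist()}: correlation undefined"
        )
    r = np.corrcoef(values)
    A = (r >= threshold).astype(float)
    np.fill_diagonal(A, 0.0)
    A = np.maximum(A, A.T)
    return CellGraph(
        adjacency=A, cell_ids=ids,
        meta={"builder": "correlation", "threshold": threshold},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_label_mask(path) -> np.ndarray:
    """Read an integer label mask from a (single-page) TIFF file."""
    import tifffile

    mask = np.asarray(tifffile.imread(path))
    if mask.ndim == 3 and mask.shape[0] == 1:
        mask = mask[0]
    return mask


def read_positions_csv(path) -> pd.DataFrame:
    """Read a headered ``cell_id,x,y[,label]`` CSV."""
    df = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"positions CSV missing column {col!r}")
    return df


def save_graph(graph: CellGraph, edge_csv, sidecar_json=None) -> None:
    """Write the edge list as ``source,target`` CSV plus a JSON sidecar."""
    edges = graph.edge_list()
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(edge_csv, index=False)
    sidecar = Path(sidecar_json) if sidecar_json else Path(edge_csv).with_suffix(".json")
    payload = {
        "n_cells": graph.n_cells,
        "n_edges": graph.n_edges,
        "cell_ids": np.asarray(graph.cell_ids).tolist(),
        **graph.meta,
    }
    sidecar.write_text(json.dumps(payload, indent=2, default=float))


def load_graph(edge_csv, sidecar_json=None) -> CellGraph:
    sidecar = Path(sidecar_json) if sidecar_json else Path(edge_csv).with_suffix(".json")
    payload = json.loads(Path(sidecar).read_text())
    cell_ids = np.asarray(payload["cell_ids"])
    n = payload["n_cells"]
    pos_of = {cid: k for k, cid in enumerate(cell_ids.tolist())}
    A = np.zeros((n, n))
    edges = pd.read_csv(edge_csv)
    for s, t in zip(edges["source"], edges["target"]):
        i, j = pos_of[s], pos_of[t]
        A[i, j] = A[j, i] = 1.0
    meta = {k: v for k, v in payload.items() if k not in ("cell_ids", "n_cells", "n_edges")}
    return CellGraph(adjacency=A, cell_ids=cell_ids, meta=meta)
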