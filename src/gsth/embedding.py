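"""Diffusion-potential trajectory embedding and condition likelihood scores.

``embed`` reduces scattering descriptors to a low-dimensional trajectory the
way diffusion-geometry methods (PHATE being the canonical example) do:

1. adaptive-bandwidth alpha-decay kernel on descriptor rows,
2. row-normalization to a diffusion operator P,
3. diffusion for t steps (t chosen automatically at the knee of the von
   Neumann entropy of the diffusion spectrum),
4. potential distances ||log P^t_i - log P^t_j||,
5. metric multidimensional scaling of the potential distances.

Every step is deterministic (classical Torgerson MDS with a fixed sign
convention), so a given input and parameter set always reproduces the same
coordinates bit for bit; the ``seed`` argument is recorded with the output so
configs stay self-describing.

``relative_likelihood`` scores each item of a two-condition population by the
ratio of per-condition kernel density estimates, the standard way to quantify
where two labelled populations overlap on a manifold (values near 0.5) versus
separate (values near 0 or 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["TrajectoryEmbedding", "LikelihoodScores", "embed", "relative_likelihood"]


@dataclass
class TrajectoryEmbedding:
    """Low-dimensional coordinates of timepoints or cells, in input order."""

    points: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LikelihoodScores:
    """Per-item likelihood of the first label of ``label_set``, in [0, 1]."""

    values: np.ndarray
    label_set: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _as_matrix(coeffs) -> np.ndarray:
    X = np.asarray(getattr(coeffs, "matrix", coeffs), dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be a 2D matrix of descriptor rows")
    if not np.isfinite(X).all():
        raise ValueError("descriptor rows must be finite")
    return X


def _alpha_decay_kernel(D: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Symmetric adaptive-bandwidth decaying kernel on a distance matrix."""
    m = D.shape[0]
    # bandwidth of each row: distance to its k-th nearest neighbour (self excluded)
    sortd = np.sort(D, axis=1)
    eps = sortd[:, min(k, m - 1)]
    eps = np.maximum(eps, 1e-12)
    with np.errstate(over="ignore"):
        Ki = np.exp(-((D / eps[:, None]) ** alpha))
    return 0.5 * (Ki + Ki.T)


def _von_neumann_entropy_knee(K: np.ndarray, t_max: int = 100) -> int:
    """Automatic diffusion time: knee of the entropy of the diffusion spectrum."""
    d = K.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    M = inv_sqrt[:, None] * K * inv_sqrt[None, :]
    lam = np.linalg.eigvalsh(M)
    lam = np.clip(lam, 0.0, None)
    ts = np.arange(1, t_max + 1)
    H = np.empty(t_max)
    for i, t in enumerate(ts):
        p = lam**t
        s = p.sum()
        if s <= 0:
            H[i] = 0.0
            continue
        p = p / s
        nz = p > 0
        H[i] = float(-(p[nz] * np.log(p[nz])).sum())
    # knee: farthest point from the chord between the endpoints of H(t)
    x0, y0, x1, y1 = ts[0], H[0], ts[-1], H[-1]
    denom = np.hypot(x1 - x0, y1 - y0)
    if denom == 0:
        return 1
    dist = np.abs((y1 - y0) * ts - (x1 - x0) * H + x1 * y0 - y1 * x0) / denom
    return int(ts[int(np.argmax(dist))])


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    """Deterministic metric MDS (Torgerson double-centering + top eigenvectors)."""
    m = D.shape[0]
    D2 = D**2
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    Y = vecs[:, order] * np.sqrt(lam)[None, :]
    # fix each axis sign: the largest-magnitude coordinate is positive
    for ax in range(Y.shape[1]):
        col = Y[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            Y[:, ax] = -col
    return Y


def embed(
    coeffs,
    dims: int = 3,
    k: int = 5,
    alpha: float = 40.0,
    t: Union[str, int] = "auto",
    seed: int = 0,
) -> TrajectoryEmbedding:
    """Diffusion-potential embedding of descriptor rows into ``dims`` axes.

    Parameters
    ----------
    coeffs : ScatteringCoefficients or (m, p) array
        One row per timepoint (time trajectories) or per cell (cell maps).
    dims : int
        Output dimensionality; 3 for the standard trajectory plots.
    k : int
        Neighbourhood size for the adaptive kernel bandwidth.
    alpha : float
        Kernel decay exponent; larger values sharpen the kernel cutoff.
    t : "auto" or int
        Diffusion time; "auto" picks the von Neumann entropy knee.
    seed : int
        Recorded in ``params``; the computation itself is deterministic.
    """
    X = _as_matrix(coeffs)
    m = X.shape[0]
    if m < dims + 1:
        raise ValueError(f"need at least dims+1={dims + 1} rows, got {m}")
    if k >= m:
        raise ValueError(f"k={k} must be smaller than the number of rows ({m})")
    D = squareform(pdist(X))
    if D.max() == 0:
        # all rows identical: zero potential distances, collapse to the origin
        return TrajectoryEmbedding(
            points=np.zeros((m, dims)),
            params={"dims": dims, "k": k, "alpha": alpha, "t": 1, "seed": seed},
        )
    K = _alpha_decay_kernel(D, k=k, alpha=alpha)
    t_used = _von_neumann_entropy_knee(K) if t == "auto" else int(t)
    if t_used < 1:
        raise ValueError("diffusion time must be >= 1")
    P = K / K.sum(axis=1, keepdims=True)
    # tiny uniform damping keeps P^t strictly positive so the log-potential
    # is finite even when the alpha-decay kernel underflows between clusters
    P = (1.0 - 1e-6) * P + 1e-6 / m
    Pt = np.linalg.matrix_power(P, t_used)
    U = -np.log(Pt)
    pot = squareform(pdist(U))
    Y = _classical_mds(pot, dims)
    return TrajectoryEmbedding(
        points=Y,
        params={"dims": dims, "k": k, "alpha": alpha, "t": int(t_used), "seed": seed},
    )


def relative_likelihood(
    embedding_input,
    labels,
    bandwidth: Union[str, float] = "auto",
) -> LikelihoodScores:
    """Per-item likelihood of the first condition from two-condition KDEs.

    For each item i, L_i = d1(x_i) / (d1(x_i) + d2(x_i)) where d_c is a
    Gaussian kernel density estimate built from the items of condition c
    (count-normalized, so conditions of unequal size are compared as
    densities).  ``bandwidth='auto'`` uses the mean distance to the k-th
    nearest neighbour with k = max(5, ceil(n/5)); that heavy smoothing plays
    the role of the low-pass filtering density-estimation methods apply on
    manifolds, so shuffled labels give scores concentrated near 0.5 rather
    than noise-dominated extremes.
    """
    X = _as_matrix(embedding_input)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must align with descriptor rows")
    label_set = np.unique(labels)
    if label_set.size != 2:
        raise ValueError(f"exactly two labels required, got {label_set.tolist()}")
    n = X.shape[0]
    masks = [labels == lab for lab in label_set]
    if min(m.sum() for m in masks) < 5:
        raise ValueError("each condition needs at least 5 items")
    D = squareform(pdist(X))
    if D.max() == 0:
        raise ValueError("all items identical: density ratio undefined")
    if bandwidth == "auto":
        k = max(5, int(np.ceil(n / 5)))
        k = min(k, n - 1)
        h = float(np.sort(D, axis=1)[:, k].mean())
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    W = np.exp(-(D**2) / (2.0 * h * h))
    d1 = W[:, masks[0]].mean(axis=1)
    d2 = W[:, masks[1]].mean(axis=1)
    tot = d1 + d2
    L = np.where(tot > 0, d1 / np.where(tot > 0, tot, 1.0), 0.5)
    return LikelihoodScores(values=L, label_set=tuple(label_set.tolist()))
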