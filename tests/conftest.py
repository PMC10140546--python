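"""Shared fixtures and independent oracles.

The oracles here are deliberately naive, literal transcriptions (dense matrix
powers, full boundary-matrix reduction over every simplex, exhaustive pair
scans) kept separate from the package's optimized code paths so the two can
be compared as independent routes to the same quantities.
"""

from itertools import combinations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# scattering oracle: literal dense transcription
# ---------------------------------------------------------------------------

def oracle_diffusion(A):
    """R = 1/2 I + 1/2 A D^-1 with identity columns for isolated vertices."""
    n = A.shape[0]
    d = A.sum(axis=0)
    R = 0.5 * np.eye(n)
    for j in range(n):
        if d[j] > 0:
            R[:, j] += 0.5 * A[:, j] / d[j]
        else:
            R[j, j] = 1.0
    return R


def oracle_wavelets(R, J):
    """Psi_0 = I - R, Psi_j = R^(2^(j-1)) - R^(2^j), via plain matrix_power."""
    n = R.shape[0]
    psis = [np.eye(n) - R]
    for j in range(1, J + 1):
        psis.append(
            np.linalg.matrix_power(R, 2 ** (j - 1)) - np.linalg.matrix_power(R, 2**j)
        )
    low = np.linalg.matrix_power(R, 2**J)
    return psis, low


def oracle_scatter_timepoint(A, X, J):
    """Per-timepoint scattering descriptor rows, channel by channel."""
    R = oracle_diffusion(A)
    psis, low = oracle_wavelets(R, J)
    T = X.shape[1]
    rows = []
    for ti in range(T):
        x = X[:, ti]
        parts = [low @ x]
        for j in range(1, J + 1):
            parts.append(low @ np.abs(psis[j] @ x))
        for j in range(1, J + 1):
            for j2 in range(j + 1, J + 1):
                parts.append(low @ np.abs(psis[j2] @ np.abs(psis[j] @ x)))
        rows.append(np.concatenate(parts))
    return np.array(rows)


def oracle_scatter_cell(A, X, J):
    """Per-cell rows: each channel applied per frame, gathered across frames."""
    R = oracle_diffusion(A)
    psis, low = oracle_wavelets(R, J)
    n, T = X.shape
    channels = [low @ X]
    for j in range(1, J + 1):
        channels.append(low @ np.abs(psis[j] @ X))
    for j in range(1, J + 1):
        for j2 in range(j + 1, J + 1):
            channels.append(low @ np.abs(psis[j2] @ np.abs(psis[j] @ X)))
    return np.concatenate(channels, axis=1)


# ---------------------------------------------------------------------------
# Rips oracle: textbook full boundary-matrix reduction
# ---------------------------------------------------------------------------

def oracle_rips(points, max_dim):
    """Persistence bars by global reduction over every simplex up to dim max_dim+1.

    Returns {q: sorted list of (birth, death, capped)} with the infinite
    features capped at the max pairwise distance; zero-length bars dropped.
    """
    P = np.asarray(points, dtype=float)
    m = len(P)
    D = np.sqrt(((P[:, None] - P[None, :]) ** 2).sum(-1))
    cap = float(D.max()) if m > 1 else 0.0

    simplices = []  # (filtration, dim, vertex tuple)
    for dim in range(0, max_dim + 2):
        for verts in combinations(range(m), dim + 1):
            f = 0.0 if dim == 0 else max(
                D[a, b] for a, b in combinations(verts, 2)
            )
            simplices.append((f, dim, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    rank = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for f, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            columns.append({rank[face] for face in combinations(verts, dim)})

    low_owner = {}
    pair_of = {}
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            if low not in low_owner:
                low_owner[low] = j
                pair_of[low] = j
                break
            col ^= columns[low_owner[low]]
        columns[j] = col

    bars = {q: [] for q in range(max_dim + 1)}
    paired_rows = set(pair_of)
    paired_cols = set(pair_of.values())
    for i, (f, dim, verts) in enumerate(simplices):
        if i in paired_rows:
            j = pair_of[i]
            death = simplices[j][0]
            if dim <= max_dim and death > f:
                bars[dim].append((f, death, False))
        elif i not in paired_cols and dim <= max_dim:
            # creator never killed: infinite feature, capped
            if cap > f or dim == 0:
                bars[dim].append((f, cap, True))
    for q in bars:
        bars[q].sort()
    return bars


def diagram_to_oracle_form(diagram, max_dim):
    out = {q: [] for q in range(max_dim + 1)}
    for b, d, q, c in zip(diagram.births, diagram.deaths, diagram.dims, diagram.capped):
        if q <= max_dim:
            out[int(q)].append((float(b), float(d), bool(c)))
    for q in out:
        out[q].sort()
    return out


def assert_bars_close(left, right, tol=1e-9):
    assert set(left) == set(right)
    for q in left:
        assert len(left[q]) == len(right[q]), f"H{q}: {left[q]} vs {right[q]}"
        for (b1, d1, c1), (b2, d2, c2) in zip(left[q], right[q]):
            assert abs(b1 - b2) < tol and abs(d1 - d2) < tol and c1 == c2


# ---------------------------------------------------------------------------
# small-graph helpers
# ---------------------------------------------------------------------------

def random_connected_adjacency(n, rng, p=0.5):
    """Random symmetric 0/1 adjacency, forced connected by a random spanning tree."""
    A = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        A[order[i], j] = A[j, order[i]] = 1.0
    extra = rng.random((n, n)) < p
    extra = np.triu(extra, 1)
    A = np.maximum(A, extra + extra.T)
    np.fill_diagonal(A, 0.0)
    return A


def brute_force_event_components(ev, A, idx_of, window_frames):
    """Connected components of the event graph by explicit pairwise BFS."""
    n = len(ev)
    adj = [[] for _ in range(n)]
    rows = list(ev.itertuples(index=False))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = idx_of[rows[i].cell_id], idx_of[rows[j].cell_id]
            if A[ci, cj] and abs(rows[i].peak_frame - rows[j].peak_frame) <= window_frames:
                adj[i].append(j)
                adj[j].append(i)
    seen = [-1] * n
    comp = 0
    for s in range(n):
        if seen[s] >= 0:
            continue
        stack = [s]
        seen[s] = comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if seen[v] < 0:
                    seen[v] = comp
                    stack.append(v)
        comp += 1
    return np.asarray(seen)
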