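"""Diffusion operator, wavelet bank, and scattering coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    oracle_scatter_cell,
    oracle_scatter_timepoint,
    random_connected_adjacency,
)
from gsth import (
    CellGraph,
    SignalMatrix,
    build_wavelet_bank,
    default_num_scales,
    diffusion_operator,
    make_lattice,
    scatter_cells,
    scatter_timepoints,
)


def graph_from_adjacency(A):
    return CellGraph(adjacency=A, cell_ids=np.arange(A.shape[0]))


def path_graph(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return graph_from_adjacency(A)


def cycle_graph(n):
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return graph_from_adjacency(A)


class TestDiffusionOperator:
    def test_k2_is_uniform(self):
        g = graph_from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(diffusion_operator(g), np.full((2, 2), 0.5))

    def test_p3_matches_formula(self):
        R = diffusion_operator(path_graph(3))
        expect = np.array([[0.5, 0.25, 0.0], [0.5, 0.5, 0.5], [0.0, 0.25, 0.5]])
        np.testing.assert_allclose(R, expect)
        np.testing.assert_allclose(R.sum(axis=0), np.ones(3))

    def test_isolated_vertex_gets_identity_column(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        R = diffusion_operator(graph_from_adjacency(A))
        np.testing.assert_allclose(R[:, 2], [0.0, 0.0, 1.0])
        np.testing.assert_allclose(R.sum(axis=0), np.ones(3))

    def test_laziness_bounds(self):
        g = path_graph(3)
        with pytest.raises(ValueError):
            diffusion_operator(g, laziness=0.0)
        with pytest.raises(ValueError):
            diffusion_operator(g, laziness=1.0)


class TestWaveletBank:
    def test_k2_idempotent_operator_kills_fine_scales(self):
        g = graph_from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        bank = build_wavelet_bank(diffusion_operator(g), J=3)
        np.testing.assert_allclose(
            bank.wavelets[0], np.array([[0.5, -0.5], [-0.5, 0.5]])
        )
        for j in range(1, 4):
            np.testing.assert_allclose(bank.wavelets[j], 0.0, atol=1e-15)

    def test_p3_first_scale_is_r_minus_r_squared(self):
        R = diffusion_operator(path_graph(3))
        bank = build_wavelet_bank(R, J=2)
        np.testing.assert_allclose(bank.wavelets[1], R - R @ R, atol=1e-14)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 50),
        J=st.integers(1, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_telescoping_and_stochasticity(self, n, J, seed):
        rng = np.random.default_rng(seed)
        g = graph_from_adjacency(random_connected_adjacency(n, rng))
        R = diffusion_operator(g)
        bank = build_wavelet_bank(R, J)
        assert bank.telescoping_residual() < 1e-10
        np.testing.assert_allclose(R.sum(axis=0), 1.0, atol=1e-12)
        assert R.min() >= 0 and R.max() <= 1
        assert bank.low_pass.min() >= -1e-15 and bank.low_pass.max() <= 1 + 1e-15

    def test_rejects_nonpositive_scales(self):
        with pytest.raises(ValueError):
            build_wavelet_bank(np.eye(3), J=0)


class TestScatterTimepoints:
    def test_constant_signal_on_regular_graph(self):
        g = cycle_graph(4)
        bank = build_wavelet_bank(diffusion_operator(g), J=2)
        sm = SignalMatrix(values=np.full((4, 3), 7.0))
        coeffs = scatter_timepoints(sm, bank)
        s0 = coeffs.matrix[:, (coeffs.index["order"] == "S0").to_numpy()]
        rest = coeffs.matrix[:, (coeffs.index["order"] != "S0").to_numpy()]
        np.testing.assert_allclose(s0, 7.0, atol=1e-12)
        np.testing.assert_allclose(rest, 0.0, atol=1e-12)

    def test_impulse_on_cycle_matches_dense_oracle(self):
        g = cycle_graph(4)
        bank = build_wavelet_bank(diffusion_operator(g), J=2)
        X = np.zeros((4, 1))
        X[1, 0] = 1.0
        got = scatter_timepoints(SignalMatrix(values=X), bank).matrix
        expect = oracle_scatter_timepoint(g.adjacency, X, J=2)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_permutation_equivariance_and_moment_invariance(self, rng):
        n, T, J = 8, 5, 3
        A = random_connected_adjacency(n, rng)
        X = rng.normal(size=(n, T))
        perm = rng.permutation(n)
        Ap = A[np.ix_(perm, perm)]
        g, gp = graph_from_adjacency(A), graph_from_adjacency(Ap)
        bank = build_wavelet_bank(diffusion_operator(g), J)
        bankp = build_wavelet_bank(diffusion_operator(gp), J)
        c = scatter_timepoints(SignalMatrix(values=X), bank)
        cp = scatter_timepoints(SignalMatrix(values=X[perm]), bankp)
        # concatenated coefficients permute with the vertices, channel by channel
        for (order, j, j2), grp in c.index.groupby(["order", "j", "j2"]).groups.items():
            cols = np.asarray(grp)
            np.testing.assert_allclose(
                cp.matrix[:, cols], c.matrix[:, cols][:, perm], atol=1e-12
            )
        m = scatter_timepoints(SignalMatrix(values=X), bank, aggregation="moments")
        mp = scatter_timepoints(SignalMatrix(values=X[perm]), bankp, aggregation="moments")
        np.testing.assert_allclose(m.matrix, mp.matrix, atol=1e-12)

    def test_first_and_second_order_nonnegative(self, rng):
        g = graph_from_adjacency(random_connected_adjacency(10, rng))
        bank = build_wavelet_bank(diffusion_operator(g), J=3)
        X = rng.normal(size=(10, 6))
        c = scatter_timepoints(SignalMatrix(values=X), bank)
        high = c.matrix[:, (c.index["order"] != "S0").to_numpy()]
        assert high.min() >= -1e-14

    def test_dimension_mismatch(self, rng):
        bank = build_wavelet_bank(diffusion_operator(path_graph(3)), J=2)
        with pytest.raises(ValueError, match="cells"):
            scatter_timepoints(SignalMatrix(values=np.ones((4, 5))), bank)


class TestScatterCells:
    def test_zero_signal_gives_zero_embeddings(self):
        bank = build_wavelet_bank(diffusion_operator(path_graph(3)), J=2)
        c = scatter_cells(SignalMatrix(values=np.zeros((3, 4))), bank)
        np.testing.assert_allclose(c.matrix, 0.0)

    def test_automorphic_cells_embed_identically(self):
        # path 0-1-2 has the mirror automorphism swapping 0 and 2
        bank = build_wavelet_bank(diffusion_operator(path_graph(3)), J=2)
        X = np.array([[1.0, 2.0, 0.5, 1.0],
                      [0.3, 0.3, 0.3, 0.3],
                      [1.0, 2.0, 0.5, 1.0]])
        c = scatter_cells(SignalMatrix(values=X), bank)
        np.testing.assert_allclose(c.matrix[0], c.matrix[2], atol=1e-12)

    def test_path_matches_dense_oracle(self):
        g = path_graph(3)
        bank = build_wavelet_bank(diffusion_operator(g), J=2)
        X = np.array([[1.0, 0.0, 2.0, 1.0],
                      [0.0, 3.0, 1.0, 0.0],
                      [2.0, 1.0, 0.0, 4.0]])
        got = scatter_cells(SignalMatrix(values=X), bank).matrix
        expect = oracle_scatter_cell(g.adjacency, X, J=2)
        np.testing.assert_allclose(got, expect, atol=1e-12)


def test_default_num_scales_tracks_diameter():
    assert default_num_scales(make_lattice(2, 2)) == 2  # diameter 2
    assert default_num_scales(make_lattice(15, 15)) == 5  # diameter 28
    assert default_num_scales(make_lattice(40, 40)) == 6  # capped
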