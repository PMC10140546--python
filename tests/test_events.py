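"""Ca2+ event detection, neighbourhood clustering, and activity statistics."""

import numpy as np
import pandas as pd
import pytest

from gsth import (
    SignalMatrix,
    cluster_events,
    detect_events,
    image_correlation,
    make_lattice,
    max_spike_duration,
    normalize_traces,
    participation_stats,
)
from gsth.events import EVENT_COLUMNS, size_class_of
from gsth.graph import CellGraph


def events_frame(rows):
    """rows: (cell_id, peak_frame) or full 7-tuples."""
    full = []
    for r in rows:
        if len(r) == 2:
            cid, pk = r
            full.append((cid, pk - 2, pk, pk + 2, 1.0, 1.5, 1.0))
        else:
            full.append(tuple(r))
    return pd.DataFrame(full, columns=EVENT_COLUMNS)


def planted_trace(T, peaks, amplitude=2.0, sigma=3.0, noise=0.0, rng=None):
    t = np.arange(T, dtype=float)
    x = np.ones(T)
    for mu in peaks:
        x += amplitude * np.exp(-((t - mu) ** 2) / (2 * sigma**2))
    if noise > 0:
        x += rng.normal(0, noise, size=T)
    return np.maximum(x, 1e-6)


class TestNormalize:
    def test_divides_by_minimum(self):
        sm = SignalMatrix(values=np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(normalize_traces(sm).values, [[1.0, 2.0, 3.0]])

    def test_constant_trace_becomes_unity(self):
        sm = SignalMatrix(values=np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(normalize_traces(sm).values, 1.0)

    def test_row_minimum_is_one(self, rng):
        sm = SignalMatrix(values=rng.uniform(0.5, 4.0, size=(6, 40)))
        out = normalize_traces(sm)
        np.testing.assert_allclose(out.values.min(axis=1), 1.0)
        assert out.normalized

    def test_nonpositive_names_cell_and_frame(self):
        values = np.ones((2, 4))
        values[1, 2] = -1.0
        with pytest.raises(ValueError, match="cell 1 .* frame 2"):
            normalize_traces(SignalMatrix(values=values, cell_ids=[0, 1]))


class TestDetectEvents:
    def test_subthreshold_noise_yields_nothing(self, rng):
        x = 1.0 + 0.05 * rng.normal(size=(3, 200))
        sm = SignalMatrix(values=np.abs(x) + 0.5, normalized=True)
        ev = detect_events(sm)
        assert len(ev) == 0

    def test_two_planted_transients_recovered(self, rng):
        noise = 0.1
        x = planted_trace(200, [60, 140], amplitude=5 * noise * 10,
                          noise=noise, rng=rng)
        sm = SignalMatrix(values=x[None, :], normalized=True)
        ev = detect_events(sm)
        assert len(ev) == 2
        assert np.abs(np.sort(ev["peak_frame"]) - [60, 140]).max() <= 1

    def test_noiseless_fit_recovers_amplitude_and_width(self):
        x = planted_trace(120, [60], amplitude=2.0, sigma=4.0)
        sm = SignalMatrix(values=x[None, :], normalized=True)
        ev = detect_events(sm)
        assert len(ev) == 1
        assert ev["amplitude"].iloc[0] == pytest.approx(2.0, rel=0.1)
        assert ev["sigma"].iloc[0] == pytest.approx(4.0, rel=0.1)
        assert ev["start_frame"].iloc[0] <= 60 <= ev["end_frame"].iloc[0]

    def test_requires_normalized_input(self, rng):
        sm = SignalMatrix(values=rng.uniform(1, 2, size=(2, 50)))
        with pytest.raises(ValueError, match="normalized"):
            detect_events(sm)

    def test_events_per_cell_are_disjoint_and_ordered(self, rng):
        x = planted_trace(300, [50, 70, 200], noise=0.05, rng=rng)
        sm = SignalMatrix(values=x[None, :], normalized=True)
        ev = detect_events(sm).sort_values("peak_frame")
        spans = ev[["start_frame", "end_frame"]].to_numpy()
        assert (spans[:, 0] <= spans[:, 1]).all()
        assert (spans[1:, 0] > spans[:-1, 1]).all()


class TestMaxSpikeDuration:
    def test_inclusive_span(self):
        ev = events_frame([("a", 10, 15, 20, 1.0, 2.0, 1.0)])
        assert max_spike_duration(ev)["a"] == 11

    def test_maximum_over_events(self):
        ev = events_frame([
            ("a", 10, 12, 14, 1.0, 1.0, 1.0),
            ("a", 30, 34, 38, 1.0, 1.0, 1.0),
        ])
        assert max_spike_duration(ev)["a"] == 9

    def test_cells_without_events_get_zero(self):
        ev = events_frame([("a", 10, 12, 14, 1.0, 1.0, 1.0)])
        out = max_spike_duration(ev, cell_ids=["a", "b"])
        assert out["b"] == 0

    def test_order_invariance_and_monotonicity(self, rng):
        rows = [("c", int(s), int(s) + 2, int(s) + int(w), 1.0, 1.0, 1.0)
                for s, w in zip(range(0, 100, 12), rng.integers(3, 10, 9))]
        ev = events_frame(rows)
        shuffled = ev.sample(frac=1.0, random_state=3)
        assert max_spike_duration(ev)["c"] == max_spike_duration(shuffled)["c"]
        bigger = pd.concat([ev, events_frame([("c", 200, 210, 260, 1.0, 1.0, 1.0)])])
        assert max_spike_duration(bigger)["c"] >= max_spike_duration(ev)["c"]


def brute_force_clusters(ev, A, idx_of, window_frames):
    """Connected components of the event graph by explicit BFS."""
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


class TestClusterEvents:
    def setup_method(self):
        self.graph = make_lattice(1, 5)  # path of 5 cells, ids 1..5

    def test_adjacent_cells_within_window_join(self):
        ev = events_frame([(1, 10), (2, 12)])  # 4 s apart at 2 s frames
        cl = cluster_events(ev, self.graph)
        assert cl.n_clusters == 1 and cl.cluster_sizes().iloc[0] == 2

    def test_window_exceeded_splits(self):
        ev = events_frame([(1, 10), (2, 16)])  # 12 s apart
        cl = cluster_events(ev, self.graph)
        assert cl.n_clusters == 2
        assert (cl.cluster_sizes() == 1).all()

    def test_chain_connects_transitively(self):
        # peaks at 0,4,8,12,16 s: consecutive pairs within 10 s
        ev = events_frame([(i + 1, 2 * i) for i in range(5)])
        cl = cluster_events(ev, self.graph)
        assert cl.n_clusters == 1 and cl.cluster_sizes().iloc[0] == 5

    def test_same_cell_events_stay_separate(self):
        ev = events_frame([(3, 10), (3, 13)])
        cl = cluster_events(ev, self.graph)
        assert cl.n_clusters == 2

    def test_unknown_cell_rejected(self):
        with pytest.raises(KeyError):
            cluster_events(events_frame([(99, 5)]), self.graph)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_components(self, trial, rng):
        n_cells = 12
        A = np.zeros((n_cells, n_cells))
        pairs = rng.random((n_cells, n_cells)) < 0.25
        A = np.triu(pairs, 1).astype(float)
        A = A + A.T
        g = CellGraph(adjacency=A, cell_ids=np.arange(n_cells))
        n_ev = int(rng.integers(5, 50))
        ev = events_frame([
            (int(rng.integers(0, n_cells)), int(rng.integers(0, 150)))
            for _ in range(n_ev)
        ])
        cl = cluster_events(ev, g, window_seconds=10, frame_interval=2)
        brute = brute_force_clusters(ev, A, {c: c for c in range(n_cells)}, 5)
        got = cl.assignments["cluster_id"].to_numpy()
        # same partition: cluster labels co-occur identically
        assert len(ev) == len(got)
        for i in range(len(ev)):
            for j in range(i + 1, len(ev)):
                assert (got[i] == got[j]) == (brute[i] == brute[j])

    def test_size_classes(self):
        assert size_class_of(1) == "1"
        assert size_class_of(2) == "2-10"
        assert size_class_of(10) == "2-10"
        assert size_class_of(11) == "11+"


class TestParticipation:
    def test_half_active(self):
        ev = events_frame([("a", 10), ("b", 20)])
        stats = participation_stats(ev, n_cells=4, duration_minutes=30)
        assert stats["percent_active"] == 50.0

    def test_empty(self):
        stats = participation_stats(events_frame([]), 10, 30)
        assert stats["percent_active"] == 0.0 and stats["mean_rate"] == 0.0

    def test_rate_arithmetic(self):
        ev = events_frame([("a", f) for f in range(10, 130, 20)])  # 6 events
        stats = participation_stats(ev, n_cells=1, duration_minutes=30)
        assert stats["rate_per_cell"]["a"] == pytest.approx(0.2)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            participation_stats(events_frame([]), 4, 0)


class TestImageCorrelation:
    def test_identity_is_one(self, rng):
        img = rng.uniform(size=(32, 32))
        assert image_correlation(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_photometric_negative_is_minus_one(self, rng):
        img = rng.uniform(size=(16, 16))
        assert image_correlation(img, 3.0 - img) == pytest.approx(-1.0, abs=1e-12)

    def test_half_overlap_matches_pearson(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:, :6] = 1.0
        b[:, 3:9] = 1.0
        expect = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert image_correlation(a, b) == pytest.approx(expect, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(2, 12, 12))
        assert image_correlation(a, b) == pytest.approx(image_correlation(b, a))

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            image_correlation(np.ones((3, 3)), np.ones((4, 4)))
        with pytest.raises(ValueError, match="constant"):
            image_correlation(np.ones((3, 3)), rng.uniform(size=(3, 3)))
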