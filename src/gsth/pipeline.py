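"""End-to-end orchestration: graph -> scattering -> trajectory -> topology.

``run_gsth`` executes the four-step time-trajectory analysis and
``run_cell_embeddings`` the per-cell variant with optional two-condition
likelihood scoring.  Every run writes its artifacts as headered CSVs plus a
JSON manifest with the fully resolved configuration, and contains nothing
time- or host-dependent, so rerunning an identical config reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import events as ev
from . import graph as gr
from . import scattering as sc
from . import topology as tp
from .embedding import embed, relative_likelihood

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GsthResult", "CellEmbeddingResult",
           "run_gsth", "run_cell_embeddings", "load_trajectory"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (fully JSON-serializable)."""

    signals_csv: Optional[str] = None
    positions_csv: Optional[str] = None
    label_mask: Optional[str] = None
    graph_builder: str = "positions"      # positions | labels | correlation
    graph_mode: str = "knn"               # for the positions builder
    graph_param: float = 5
    correlation_threshold: Optional[float] = None
    mask_gap: int = 1
    normalize: bool = True
    frame_interval: float = 2.0
    J: Optional[int] = None               # None -> diameter-based default
    laziness: float = 0.5
    aggregation: str = "concatenate"
    dims: int = 3
    knn: int = 5
    decay: float = 40.0
    diffusion_time: str | int = "auto"
    seed: int = 0
    max_dim: int = 1
    betti_grid: int = 100
    prominence_mad: float = 3.0
    min_separation: int = 3
    window_seconds: float = 10.0
    out_dir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class GsthResult:
    coeffs: sc.ScatteringCoefficients
    trajectory: np.ndarray
    diagram: tp.PersistenceDiagram
    betti: dict
    graph: gr.CellGraph


@dataclass
class CellEmbeddingResult:
    coeffs: sc.ScatteringCoefficients
    embedding: np.ndarray
    likelihood: Optional[np.ndarray]
    label_set: Optional[tuple]
    graph: gr.CellGraph


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", stage, exc)
                return False
            logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - self.t0)
            return False

    return _T()


def _build_graph(config: RunConfig, signals: sc.SignalMatrix) -> gr.CellGraph:
    if config.graph_builder == "labels":
        mask = gr.read_label_mask(config.label_mask)
        return gr.build_graph_from_labels(mask, gap=config.mask_gap)
    if config.graph_builder == "positions":
        df = gr.read_positions_csv(config.positions_csv)
        return gr.build_graph_from_positions(
            df[["x", "y"]].to_numpy(), mode=config.graph_mode,
            param=config.graph_param, cell_ids=df["cell_id"].to_numpy(),
        )
    if config.graph_builder == "correlation":
        if config.correlation_threshold is None:
            raise ValueError("correlation graph requires an explicit threshold")
        return gr.build_graph_from_correlation(signals, config.correlation_threshold)
    raise ValueError(f"unknown graph builder {config.graph_builder!r}")


def _prepare(config: RunConfig, signals=None, graph=None):
    if signals is None:
        with _timed("load-signals"):
            signals = sc.read_signals_csv(config.signals_csv,
                                          frame_interval=config.frame_interval)
    if config.normalize and not signals.normalized:
        with _timed("normalize"):
            signals = ev.normalize_traces(signals)
    if graph is None:
        with _timed("graph"):
            graph = _build_graph(config, signals)
    if graph.n_cells != signals.n_cells:
        raise ValueError(
            f"graph has {graph.n_cells} cells but signals have {signals.n_cells}"
        )
    J = config.J if config.J is not None else sc.default_num_scales(graph)
    with _timed("wavelets"):
        R = sc.diffusion_operator(graph, laziness=config.laziness)
        bank = sc.build_wavelet_bank(R, J, laziness=config.laziness)
    return signals, graph, bank


def run_gsth(config: RunConfig, signals=None, graph=None) -> GsthResult:
    """Full time-trajectory analysis; optionally writes artifacts to out_dir."""
    signals, graph, bank = _prepare(config, signals, graph)
    with _timed("scatter-timepoints"):
        coeffs = sc.scatter_timepoints(signals, bank, aggregation=config.aggregation)
    with _timed("embed"):
        emb = embed(coeffs, dims=config.dims, k=config.knn, alpha=config.decay,
                    t=config.diffusion_time, seed=config.seed)
    with _timed("topology"):
        diagram = tp.rips_persistence(emb.points, max_dim=config.max_dim)
        betti = {
            q: tp.betti_curve(
                diagram, q,
                np.linspace(0.0, diagram.cap if diagram.cap > 0 else 1.0,
                            config.betti_grid),
            )
            for q in range(config.max_dim + 1)
        }
    result = GsthResult(coeffs=coeffs, trajectory=emb.points, diagram=diagram,
                        betti=betti, graph=graph)
    if config.out_dir:
        _write_gsth(config, result, emb)
    return result


def run_cell_embeddings(config: RunConfig, labels=None, signals=None,
                        graph=None) -> CellEmbeddingResult:
    """Per-cell embedding analysis with optional two-condition likelihood."""
    signals, graph, bank = _prepare(config, signals, graph)
    with _timed("scatter-cells"):
        coeffs = sc.scatter_cells(signals, bank)
    with _timed("embed"):
        emb = embed(coeffs, dims=config.dims, k=config.knn, alpha=config.decay,
                    t=config.diffusion_time, seed=config.seed)
    likelihood = None
    label_set = None
    if labels is not None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) == 2:
            with _timed("likelihood"):
                scores = relative_likelihood(coeffs, labels)
            likelihood = scores.values
            label_set = scores.label_set
        else:
            logger.info("likelihood skipped: need exactly two label values, "
                        "got %d", len(np.unique(labels)))
    result = CellEmbeddingResult(coeffs=coeffs, embedding=emb.points,
                                 likelihood=likelihood, label_set=label_set,
                                 graph=graph)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(emb.points, columns=[f"E{i+1}" for i in range(config.dims)])
        df.insert(0, "cell_id", coeffs.item_ids)
        df.to_csv(out / "cell_embedding.csv", index=False)
        if likelihood is not None:
            pd.DataFrame({
                "cell_id": coeffs.item_ids, "label": labels,
                "likelihood": likelihood,
            }).to_csv(out / "likelihood.csv", index=False)
        (out / "manifest.json").write_text(config.to_json())
    return result


def _write_gsth(config: RunConfig, result: GsthResult, emb) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gr.save_graph(result.graph, out / "graph_edges.csv")
    traj = pd.DataFrame(result.trajectory,
                        columns=[f"E{i+1}" for i in range(result.trajectory.shape[1])])
    traj.insert(0, "t", np.arange(len(traj)))
    traj.to_csv(out / "trajectory.csv", index=False)
    result.diagram.to_csv(out / "persistence_diagram.csv")
    for q, curve in result.betti.items():
        curve.to_frame().to_csv(out / f"betti_h{q}.csv", index=False)
    manifest = json.loads(config.to_json())
    manifest["embedding_params"] = emb.params
    manifest["J_used"] = int(result.coeffs.J)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_trajectory(path) -> np.ndarray:
    """Re-load a saved trajectory CSV as an (m, dims) coordinate array."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("E")]
    return df[cols].to_numpy(dtype=float)
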