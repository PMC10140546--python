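"""Graph wavelets and geometric scattering coefficients.

The Ca2+ level of each cell at one frame is a signal x(v, t) on the cellular
graph.  A lazy random-walk operator

    R = laziness * I + (1 - laziness) * A D^{-1}          (laziness = 1/2)

drives a bank of diffusion wavelets

    Psi_0 = I - R,      Psi_j = R^{2^{j-1}} - R^{2^j},    1 <= j <= J,

which decompose a signal into dyadic spatial scales; the residual low-pass is
R^{2^J}, and the bank telescopes back to the identity.  Scattering
coefficients are built from these by a cascade of wavelet transforms and
modulus nonlinearities, all followed by the low-pass:

    S_0        = R^{2^J} x
    S_1(j)     = R^{2^J} |Psi_j x|
    S_2(j, j') = R^{2^J} |Psi_j' |Psi_j x||,   j < j'.

Two embedding modes share this machinery: *timepoint* mode treats each frame
as a separate graph signal and yields one descriptor row per frame (used for
time trajectories), *cell* mode gathers each cell's coefficients across every
frame and yields one descriptor row per cell (used to compare cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .graph import CellGraph

__all__ = [
    "SignalMatrix",
    "WaveletBank",
    "ScatteringCoefficients",
    "diffusion_operator",
    "build_wavelet_bank",
    "scatter_timepoints",
    "scatter_cells",
    "default_num_scales",
    "read_signals_csv",
    "write_signals_csv",
]


@dataclass
class SignalMatrix:
    """A cells x frames fluorescence matrix.

    ``frame_interval`` is the acquisition period in seconds (2 s by default,
    the usual cadence for basal-layer recordings).  ``normalized`` marks
    traces already divided by their per-cell minimum (F/F_min), in which case
    every row minimum is 1.
    """

    values: np.ndarray
    frame_interval: float = 2.0
    normalized: bool = False
    cell_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (cells x frames)")
        if not np.isfinite(self.values).all():
            raise ValueError("signal values must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape[0] != self.values.shape[0]:
                raise ValueError("cell_ids length must match number of rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_minutes(self) -> float:
        return self.n_frames * self.frame_interval / 60.0


@dataclass
class WaveletBank:
    """Diffusion operator, wavelets Psi_0..Psi_J, and low-pass R^(2^J)."""

    R: np.ndarray
    J: int
    wavelets: List[np.ndarray]
    low_pass: np.ndarray
    laziness: float = 0.5

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    def telescoping_residual(self) -> float:
        """Max-norm of Psi_0 + sum_j Psi_j + R^(2^J) - I (0 in exact arithmetic)."""
        total = sum(self.wavelets) + self.low_pass
        return float(np.abs(total - np.eye(self.n_cells)).max())


@dataclass
class ScatteringCoefficients:
    """Scattering descriptors, one row per timepoint or per cell.

    ``index`` describes each column: coefficient order, scales (j, j2) and the
    vertex slot (timepoint mode) or frame slot (cell mode), or the moment
    number under moment aggregation.
    """

    matrix: np.ndarray
    mode: str  # "timepoint" | "cell"
    index: pd.DataFrame
    J: int
    aggregation: str = "concatenate"
    item_ids: Optional[np.ndarray] = None

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]


def diffusion_operator(graph: CellGraph, laziness: float = 0.5) -> np.ndarray:
    """Column-stochastic lazy random-walk operator on the cellular graph.

    R = laziness * I + (1 - laziness) * A D^{-1}.  A degree-0 vertex gets a
    pure self-loop (identity column) so the operator stays column-stochastic.
    """
    if not (0.0 < laziness < 1.0):
        raise ValueError("laziness must be in (0, 1)")
    A = graph.adjacency
    d = graph.degrees
    n = graph.n_cells
    inv_d = np.zeros(n)
    nz = d > 0
    inv_d[nz] = 1.0 / d[nz]
    R = laziness * np.eye(n) + (1.0 - laziness) * (A * inv_d[None, :])
    # isolated vertices: the (1 - laziness) mass has nowhere to go; keep it home
    iso = np.nonzero(~nz)[0]
    R[iso, iso] = 1.0
    return R


def build_wavelet_bank(R: np.ndarray, J: int, laziness: float = 0.5) -> WaveletBank:
    """Dyadic wavelets Psi_0 = I - R, Psi_j = R^(2^(j-1)) - R^(2^j), j = 1..J.

    Powers are computed by repeated squaring, so only J matrix products are
    needed and the telescoping identity holds to machine precision.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    wavelets = [np.eye(n) - R]
    power = R  # R^(2^0)
    for _ in range(1, J + 1):
        nxt = power @ power
        wavelets.append(power - nxt)
        power = nxt
    return WaveletBank(R=R, J=J, wavelets=wavelets, low_pass=power, laziness=laziness)


def default_num_scales(graph: CellGraph, cap: int = 6) -> int:
    """Default wavelet scale count: min(cap, ceil(log2(diameter + 1))).

    The largest wavelet then has support comparable to the tissue width.
    Diameter is taken over the largest connected component.
    """
    from scipy.sparse.csgraph import shortest_path

    sp = shortest_path(graph.adjacency, method="D", unweighted=True)
    finite = sp[np.isfinite(sp)]
    diam = int(finite.max()) if finite.size else 0
    return max(1, min(cap, int(np.ceil(np.log2(diam + 1))) if diam > 0 else 1))


def _scatter_channels(values: np.ndarray, bank: WaveletBank):
    """All scattering channels of an (n_cells, T) signal block.

    Returns a list of ``(label, (n_cells, T) array)`` in canonical order:
    S0, S1(1..J), S2(j,j') for j < j'.  Each array holds the channel evaluated
    at every vertex and frame.
    """
    low = bank.low_pass
    out = [(("S0", 0, 0), low @ values)]
    firsts = []
    for j in range(1, bank.J + 1):
        u = np.abs(bank.wavelets[j] @ values)
        firsts.append(u)
        out.append((("S1", j, 0), low @ u))
    for j in range(1, bank.J + 1):
        for j2 in range(j + 1, bank.J + 1):
            out.append((("S2", j, j2), low @ np.abs(bank.wavelets[j2] @ firsts[j - 1])))
    return out


def _check_compatible(signals: SignalMatrix, bank: WaveletBank) -> None:
    if signals.n_cells != bank.n_cells:
        raise ValueError(
            f"signal matrix has {signals.n_cells} cells but wavelet bank "
            f"expects {bank.n_cells}"
        )


def scatter_timepoints(
    signals: SignalMatrix, bank: WaveletBank, aggregation: str = "concatenate"
) -> ScatteringCoefficients:
    """One scattering descriptor row per frame.

    With ``aggregation='concatenate'`` (the default) the descriptor of frame t
    is every channel evaluated at every vertex; with ``'moments'`` each channel
    is reduced to its first four raw moments across vertices, which makes
    descriptors comparable across recordings with different cell counts.
    """
    _check_compatible(signals, bank)
    channels = _scatter_channels(signals.values, bank)
    rows_meta = []
    blocks = []
    if aggregation == "concatenate":
        for (order, j, j2), arr in channels:
            blocks.append(arr.T)  # (T, n_cells)
            for v in range(bank.n_cells):
                rows_meta.append((order, j, j2, v))
        colnames = ["order", "j", "j2", "vertex"]
    elif aggregation == "moments":
        for (order, j, j2), arr in channels:
            moments = np.stack([(arr**m).mean(axis=0) for m in (1, 2, 3, 4)], axis=1)
            blocks.append(moments)  # (T, 4)
            for m in (1, 2, 3, 4):
                rows_meta.append((order, j, j2, m))
        colnames = ["order", "j", "j2", "moment"]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    matrix = np.concatenate(blocks, axis=1)
    index = pd.DataFrame(rows_meta, columns=colnames)
    return ScatteringCoefficients(
        matrix=matrix, mode="timepoint", index=index, J=bank.J,
        aggregation=aggregation, item_ids=np.arange(signals.n_frames),
    )


def scatter_cells(signals: SignalMatrix, bank: WaveletBank) -> ScatteringCoefficients:
    """One scattering descriptor row per cell.

    Wavelets act on each frame's spatial signal exactly as in timepoint mode;
    the coefficients of cell v at every frame and channel are then gathered
    into a single row, so the row encodes that cell's signalling (and its
    neighbourhood's) across the whole recording.
    """
    _check_compatible(signals, bank)
    channels = _scatter_channels(signals.values, bank)
    blocks = []
    rows_meta = []
    for (order, j, j2), arr in channels:
        blocks.append(arr)  # (n_cells, T)
        for t in range(signals.n_frames):
            rows_meta.append((order, j, j2, t))
    matrix = np.concatenate(blocks, axis=1)
    index = pd.DataFrame(rows_meta, columns=["order", "j", "j2", "frame"])
    return ScatteringCoefficients(
        matrix=matrix, mode="cell", index=index, J=bank.J,
        aggregation="concatenate", item_ids=np.asarray(signals.cell_ids),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_signals_csv(path, frame_interval: float = 2.0, normalized: bool = False) -> SignalMatrix:
    """Read a headered ``cell_id,f0,f1,...`` trace CSV."""
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError("signals CSV must have a cell_id column")
    ids = df["cell_id"].to_numpy()
    values = df.drop(columns="cell_id").to_numpy(dtype=float)
    return SignalMatrix(values=values, frame_interval=frame_interval,
                        normalized=normalized, cell_ids=ids)


def write_signals_csv(signals: SignalMatrix, path) -> None:
    cols = [f"f{i}" for i in range(signals.n_frames)]
    df = pd.DataFrame(signals.values, columns=cols)
    df.insert(0, "cell_id", signals.cell_ids)
    df.to_csv(path, index=False)
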