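# gsth — Geometric Scattering Trajectory Homology

Analytics for tissue-scale Ca²⁺ imaging: turn a (cells × time) fluorescence
matrix living on a cellular graph into multiscale signalling descriptors,
low-dimensional signalling trajectories, and topological summaries that can
be compared quantitatively across recordings — plus the conventional
per-cell event statistics (spike detection, neighbourhood clustering,
participation rates, image correlation) used alongside them.

It is written for people who record intracellular Ca²⁺ (or any per-cell
dynamic signal) across thousands of cells — epithelial sheets, neuronal
populations — and want an unsupervised, permutation-invariant way to ask:
is signalling here spatiotemporally coordinated, and does a perturbation
change that?

## The method

Given a graph G with adjacency A and degrees D, and a signal x(v, t):

1. **Cellular graph** — from a segmentation label mask (region contact),
   cell positions (kNN/radius), or trace correlations (neurons).
2. **Geometric scattering** — lazy diffusion operator R = ½(I + AD⁻¹),
   wavelets Ψ₀ = I − R, Ψⱼ = R^(2^(j−1)) − R^(2^j), and coefficients
   S₀ = R^(2^J)x, S₁(j) = R^(2^J)|Ψⱼx|, S₂(j,j′) = R^(2^J)|Ψⱼ′|Ψⱼx||,
   giving one descriptor row per timepoint (time mode) or per cell (cell
   mode).
3. **Trajectory embedding** — diffusion-potential dimensionality reduction
   (adaptive α-decay kernel → diffusion operator → entropy-knee diffusion
   time → log-potential distances → metric MDS) into 3D.
4. **Topology** — Vietoris–Rips persistence diagrams of the trajectory,
   Betti curves, and exact 2-Wasserstein distances between diagrams.
   Smooth, coordinated signalling yields trajectories whose loops are born
   at large scales; disorganized signalling yields point-cloud trajectories
   whose loops form and close early.

Cell-mode embeddings add a per-cell condition likelihood
L = d₁/(d₁ + d₂) from two-condition kernel density estimates (≈0.5 where
two labelled populations overlap).

A synthetic generator with planted ground truth (isolated spikers,
propagating cluster waves, tissue-wide waves, synchronous oscillation,
uniform noise) makes every stage testable offline.

## Worked example

```python
import numpy as np
from gsth import (SimulationSpec, simulate, diffusion_operator,
                  build_wavelet_bank, default_num_scales, scatter_timepoints,
                  embed, rips_persistence, wasserstein)

# a coordinated-wave recording and an unstructured control, 15x15 cells
wave = simulate(SimulationSpec(regime="cluster_wave", seed=100, rows=15,
                               cols=15, n_frames=200))
ctrl = simulate(SimulationSpec(regime="uniform_random", seed=200, rows=15,
                               cols=15, n_frames=200))

def trajectory_diagram(res):
    bank = build_wavelet_bank(diffusion_operator(res.graph),
                              default_num_scales(res.graph))
    coeffs = scatter_timepoints(res.signals, bank)
    return rips_persistence(embed(coeffs).points, max_dim=1)

dg_wave, dg_ctrl = trajectory_diagram(wave), trajectory_diagram(ctrl)
print("median H1 birth, wave:   %.2f" % np.median(dg_wave.bars_of(1)[:, 0]))
print("median H1 birth, control: %.2f" % np.median(dg_ctrl.bars_of(1)[:, 0]))
print("W2(H0) wave vs control:  %.1f" % wasserstein(dg_wave, dg_ctrl, 0))
```

Output:

```
median H1 birth, wave:   6.99
median H1 birth, control: 0.46
W2(H0) wave vs control:  68.7
```

The wave recording's trajectory only forms loops at large scales (median
H₁ birth 7.0) — the signature of smooth, coordinated signal spread —
while the uniform control's loops appear at tiny scales (0.5), and the two
trajectories are far apart in diagram space.

The same analyses are available from a shell via the `gsth` CLI
(`simulate`, `graph`, `scatter`, `embed`, `topology`, `events`, `run`,
`compare`); see `gsth --help`.

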