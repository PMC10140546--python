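# Methods

## The problem this package addresses

Tissue-scale Ca²⁺ imaging produces a fluorescence trace per cell on a sheet
of cells whose spatial arrangement matters: signals spread between
neighbours, so a description of the recording must be tied to the cellular
graph, yet remain comparable across tissues with different cell counts and
layouts. The package implements a four-step analysis — graph construction,
geometric scattering, diffusion-potential trajectory embedding, persistent
homology — plus conventional per-cell event analytics and a synthetic
generator that makes the whole stack testable without microscope data.

## Cellular graphs

Vertices are cells; edges are undirected and unweighted. Three builders:

* **Label masks.** Two segmented regions are adjacent when some pixel pair
  is within city-block distance `gap` (default 1 = shared border). Corner
  contact alone does not connect regions, so a tiling of squares yields the
  rook lattice; a larger `gap` absorbs hairline segmentation gaps. Positions
  are unweighted pixel centroids, 0-based `(x=col, y=row)`.
* **Positions.** kNN (union-symmetrized, ties by lower index) or a fixed
  radius.
* **Trace correlation.** Edge iff Pearson r of two traces ≥ threshold; meant
  for neurons, where physical adjacency is uninformative. The threshold has
  no default: it is a modelling decision the caller must make explicitly.

Isolated cells are kept; diffusion treats them as pure self-loops.

## Geometric scattering

With adjacency `A` and degrees `D`, the lazy random-walk operator is
`R = ½(I + A D⁻¹)` (column-stochastic; an isolated vertex gets an identity
column). Wavelets are differences of dyadic diffusion powers,
`Ψ₀ = I − R`, `Ψⱼ = R^(2^(j−1)) − R^(2^j)`, with low-pass `R^(2^J)`; the
bank telescopes to the identity, which is verified to 1e−10 in tests.
Scattering coefficients are `S₀ = R^(2^J)x`, `S₁(j) = R^(2^J)|Ψⱼx|`,
`S₂(j,j′) = R^(2^J)|Ψⱼ′|Ψⱼx||` for `j < j′`.

*Timepoint mode* treats each frame as one graph signal and concatenates all
channels over vertices into one row per frame. *Cell mode* gathers each
cell's channel values across every frame into one row per cell. Per-vertex
concatenation is the default because it follows the coefficient definitions
literally; a `moments` aggregation (first four raw moments over vertices)
is offered for comparing recordings with different cell counts, since the
two conventions appear in the literature and neither is canonical.

`J` defaults to `min(6, ceil(log2(diameter + 1)))`, so the coarsest wavelet
has support comparable to the tissue width; powers are computed densely by
repeated squaring (cell counts here are at most a few thousand, where dense
algebra is exact, fast and reproducible).

## Trajectory embedding

`embed` follows the standard diffusion-potential recipe: an
adaptive-bandwidth α-decay kernel (bandwidth = distance to the k-th
neighbour, defaults k=5, α=40), row-normalization to a diffusion operator,
diffusion time chosen at the knee of the von Neumann entropy of the
diffusion spectrum, log-potential distances, then classical (Torgerson)
metric MDS into 3 dimensions. Every step is deterministic, with a fixed
per-axis sign convention, so repeated runs are bit-identical; the `seed`
argument is recorded in the output parameters for provenance. A tiny
uniform damping (1e−6) keeps the diffusion operator strictly positive so
log-potentials stay finite even across kernel underflow between well
separated clusters.

`relative_likelihood` scores a two-condition population as
`L = d₁/(d₁+d₂)` from per-condition Gaussian kernel density estimates on
the descriptor rows (not on the 3D view, so scores do not depend on MDS
orientation). The automatic bandwidth is the mean distance to the k-th
neighbour with `k = max(5, ⌈n/5⌉)`: the deliberately heavy smoothing plays
the role of the low-pass filtering manifold density estimators apply, and
a calibration on unstructured populations shows shuffled labels then score
within a few hundredths of 0.5 while fully separated populations still
saturate to 0/1. Densities are count-normalized, so unequal condition sizes
compare as densities, not abundances. Swapping the two labels maps L to
1−L exactly.

## Persistent homology

`rips_persistence` computes the Vietoris–Rips filtration of the embedded
trajectory under Euclidean distance, from 0 until the complex is complete.
H₀ comes from union-find over sorted edges; H₁/H₂ from exact GF(2)
boundary-matrix reduction (bitset columns, compiled with numba), one
dimension at a time — a column's pivot is always a creator simplex one
dimension down, so dimensions decouple. The single infinite H₀ component is
capped at the maximum pairwise distance and flagged; zero-persistence bars
are dropped. H₂ enumerates all 3-simplices and is intended for small point
sets (the default `max_dim` is 1, matching the loop-based analyses).

Betti curves count bars alive at each threshold (`birth ≤ ε < death`) on a
default grid of 100 thresholds from 0 to the cap; capped bars are treated
as never dying there, since their true death is infinite, while Wasserstein
computations use the capped finite value so transport costs are defined.

The 2-Wasserstein distance between diagrams is solved exactly as an
assignment problem on the diagonally-augmented cost matrix (each bar may
match a bar of the other diagram or its orthogonal diagonal projection;
costs are squared Euclidean; the result is the square root of the minimum
total). Symmetry, triangle inequality and the closed-form single-bar cases
are covered by tests.

## Event analytics

Traces are normalized per cell to their own minimum (F/F_min; baseline
exactly 1). Detection runs `find_peaks` on a Gaussian-smoothed copy of the
trace (default 2-frame smoothing) with two gates, both in units of the
median absolute deviation of the raw-minus-smoothed residual:
prominence ≥ 3×MAD and peak height ≥ trace median + 3×MAD. The height gate
is essential: in a pure-noise trace the tallest local maximum has
prominence equal to the whole trace range, so prominence alone always
admits it. The residual-based MAD keeps the threshold anchored to the raw
noise level rather than the smoothed one, placing it near six standard
deviations of the smoothed noise — chance peaks essentially never qualify
while transients a few frames wide lose little amplitude. Each retained
peak is then fit by least squares on the **raw** trace with
`baseline + A·exp(−(t−μ)²/2σ²)` on a window of ±5 half-prominence
half-widths; event extent is where the fit falls to baseline + 0.1·A
(μ ± 2.146σ), clipped to the recording, with inclusive frame spans
(end − start + 1). A failed fit falls back to sample-based half-prominence
crossings with a logged warning. Overlapping fitted extents of one cell are
clipped at the midpoint between peaks so per-cell events stay disjoint.

Neighbourhood clustering connects two events when their cells are direct
graph neighbours and their **peak** times differ by ≤ 10 s (the window and
the 2-s frame interval are parameters); clusters are connected components,
sized by distinct cells and classed 1 / 2–10 / 11+. Peak times rather than
onsets are used because detection localizes peaks much more precisely than
onsets; a cell is not its own neighbour, so repeated spiking of an isolated
cell yields size-1 clusters. Participation statistics report the percent of
cells with ≥1 event and spikes/minute overall and by size class. The image
correlation coefficient is plain Pearson r over pixels of two equal-shape
images (identical images give exactly 1.0).

## Synthetic recordings

The generator plants Gaussian transients (amplitude 2.0 over baseline 1,
width σ = 3 frames) on a rook lattice (default 15×15, 200 frames at 2
s/frame) and returns the complete planted truth. Regimes: `isolated`
(per-cell Poisson events, default 0.02 events/cell/min), `cluster_wave`
(seed events recruit each neighbour with probability 0.9 at 1 frame/hop up
to 2 hops — the 2–10-cell neighbourhoods), `icw` (recruitment probability 1
and lattice-spanning radius — waves across hundreds of cells),
`synchronous` (one shared periodic train, default period 50 frames), and
`uniform_random` (every value i.i.d. Uniform(0,1), the unstructured
control). Gaussian noise (default SD 0.05) is added except in the uniform
regime.

Two design rules keep the planted truth recoverable in principle: event
peaks stay ≥ 2σ inside the recording (a transient cut by the boundary is
not a complete event), and each cell has a refractory period of 5σ frames
across all waves, so no cell carries two overlapping transients that no
detector could separate. Ground-truth neighbourhoods are defined by
applying the same adjacency + 10-s rule to the planted event list (wave
ids are kept separately), which makes "exact recovery at zero noise" a
well-posed statement even when independent events abut in space-time.

What the simulator does *not* emulate: biophysical Ca²⁺ kinetics,
photobleaching, motion, segmentation errors, cell-cycle-dependent behaviour,
or amplitude heterogeneity. Passing tests therefore demonstrate
correctness of the analysis machinery on signals with known structure, not
performance on raw microscope data.

All randomness flows from one mandatory seed through per-purpose and
per-cell child streams, so outputs are reproducible and order-independent.

## Problem sizes and numerical choices

Tests and the acceptance script run on 12×12–15×15 lattices with 200
frames and 10 replicates per regime — large enough that waves, clusters
and trajectory loops are unambiguous, while a full run stays in the
minutes range on one CPU. Other fixed choices: telescoping verified at
1e−10; kernel bandwidth floor 1e−12; Rips tie-breaks by stable sort with
edges ordered (length, index); assignment "infinity" 1e18; detection MAD
floor 1e−6 × trace range so noiseless traces keep a positive threshold.

## Known limitations

* H₂ is exact but enumerative (O(m⁴) tetrahedra): use on desk-scale clouds.
* The embedding is a self-contained diffusion-potential implementation; it
  follows the published recipe but is not numerically identical to any
  specific released implementation of PHATE, and likelihoods are likewise a
  KDE-based analogue of graph-filtered density estimators such as MELD.
* Correlation graphs use full-length Pearson r; lagged or partial
  correlations are out of scope.
* Detection assumes positive-going transients on a slowly varying baseline;
  strongly drifting baselines should be corrected upstream.
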