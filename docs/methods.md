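# Methods

This note documents the models, parameter choices and numerical conventions
behind `monnet`, and what the synthetic validation does and does not show
about real recordings.

## Synthetic MoNNet model

The simulator is a phenomenological stand-in for live recordings of
spheroid cultures. It is built to reproduce the *statistical signatures* the
analysis relies on — near-deterministic co-activity inside a spheroid,
distance-decaying coupling between spheroids, a three-stage global-synchrony
trajectory, and a genotype knob that selectively weakens global coupling —
not the biophysics that produces them.

**Layout.** Spheroid radii are log-normal (location 3.6, scale 0.25 in
log-µm, i.e. a median radius of ~37 µm) to mimic the varied spheroid sizes
seen in culture. Centroids are rejection-sampled uniformly in a square
field (default 600 µm) subject to non-overlap (centre separation ≥ sum of
radii + 10 µm clearance); an unplaceable spheroid raises a packing error
naming it. Neurons (default 6 per spheroid) are uniform in each spheroid's
disc. Everything is deterministic given the seed.

**Activity.** Each spheroid emits Poisson events (default 0.05 events/s).
An event recruits each member neuron with probability `p_local` (0.9) and
propagates — single hop, no relaying — to spheroid *b* at distance *d* with
probability `rho * w_global * exp(-d / lambda_decay)` (defaults 1.0, 0.95,
1500 µm), recruiting members of *b* in the same frame. Single-hop
propagation keeps the dependence structure analyzable; it understates the
cascades a recurrent culture can produce and is a known limitation.

**Fluorescence.** Spikes drive a stable AR(2) kernel
`c_t = g1 c_{t-1} + g2 c_{t-2} + s_t` with defaults g1 = 1.7, g2 = −0.712
(root pair ≈ 0.95/0.75 per frame: a fast-indicator decay at 30 Hz), and
`F = f0 (1 + c) + eps` with i.i.d. Gaussian noise (SD 0.03 at f0 = 1).
Spike amplitudes are fixed at 1; amplitude heterogeneity, photobleaching
drift, and movement artefacts are not modelled (the sliding baseline
downstream would absorb slow drift).

**Default regime.** The defaults were fixed once so that the wild-type
preset sits in the synchronized regime the analysis assumes: local mean
pairwise r ≈ 0.9, global ≈ 0.7, with clear directional contrasts
(phase II > phase I global efficiency; mutant ρ = 0.2 lowers efficiency and
raises module count while local synchrony moves < 0.1). With ~0.05 events/s
per spheroid and ~4-fold propagation amplification this gives per-neuron
event rates of ~15–25/min over a 2-minute recording — enough events for
stable correlation estimates at that duration.

**Phase presets.** `phaseI` (pre-synchronization) sets `w_global = 0.05`;
`phaseII`/`wt` (synchronized) 0.95; `phaseIII` (post-synchronization) uses a
block-structured coupling matrix — full propagation within each of three
super-modules, 0.05 across — with a denser event train (0.1 events/s) and
tighter recruitment (`p_local = 0.95`). The sharper phase-III parameters are
deliberate: at the fixed 0.7 co-classification cutoff the planted hierarchy
is identifiable only when in-group correlations sit clearly above 0.7, and
with softer coupling the super-modules fragment in a substantial fraction of
2-minute recordings. Phases are presets, not emergent development.

**Rendering.** Each neuron contributes an isotropic Gaussian footprint
(default SD 6 µm) scaled by its fluorescence, plus optional pixel noise.
This is sufficient for validating segmentation/aggregation round trips; it
does not model optical sectioning, scattering, or overlapping 3D somata.

## Trace processing

- **Baseline**: the 8th percentile of the raw trace in a 500-frame window
  centered on each frame. The window is truncated at the recording edges so
  the baseline is defined everywhere (the alternative — undefined leading and
  trailing 250 frames — would discard ~17 s of a 4.5-min recording). For an
  even window the centre is taken as 249 frames back / 250 forward.
- **∂F/F** = (F − baseline)/baseline. Sources whose baseline falls below
  1e−9 anywhere are flagged, set to NaN, and excluded from all sample
  averages (logged).
- **Denoising**: per-source width-3 median filter, reflected edges.
- **Onset inference**: the AR(2) model is exactly invertible, so
  `d_t = y_t − g1 y_{t−1} − g2 y_{t−2}` equals the onset train for a
  noiseless trace. Candidate onset frames are taken where `d` exceeds 3
  robust SDs of `d` (MAD × 1.4826; a tiny absolute floor covers the
  noiseless case), and amplitudes are then refit by nonnegative least
  squares on the truncated impulse-response columns, which zeroes spurious
  candidates. On noiseless traces with spikes ≥ 20 frames apart recovery is
  exact (amplitude RMSE < 1e−6, verified in the acceptance suite). When
  g1/g2 are unknown they are estimated by a Yule–Walker-style regression on
  autocovariance lags 1–5 (median across sources) projected just inside the
  stability triangle. This solver honours the generative-model contract; it
  is not intended to be numerically identical to any particular published
  deconvolution implementation.
- **Significant events**: onset amplitude strictly greater than 5 robust SDs
  of the per-source residual (∂F/F minus the AR(2) reconstruction). The
  threshold is applied to onset amplitudes, not to the ∂F/F trace — the
  residual SD is insensitive to transients, and amplitudes at exactly 5 SD
  are excluded (strict inequality, a deterministic boundary).
- **Clustered activity duration**: from each significant onset, iterative
  forward traversal to the local ∂F/F peak, then the contiguous run of
  frames at or above `level × peak` (level 0.75 or 0.5, relative to the
  ∂F/F baseline of 0) around it, in integer frames converted to seconds.
  Later onsets falling inside an already-analyzed run are skipped. Widths
  are per-source means, then averaged over sources with at least one event.

## Graphs and modules

Pairwise Pearson correlation of ∂F/F over all source pairs; constant or
flagged traces are masked and excluded from graphs entirely (counts
logged). Local/global synchrony averages within-/across-spheroid pairs;
with one spheroid the global mean is reported missing, never 0. Binary
graphs use `r ≥ threshold` (boundary inclusive, deterministic); the routine
thresholds 0.5 / 0.7 / 0.8 are positive, so negative correlations never
form edges. Efficiency follows the standard definitions (global: mean
inverse shortest-path length; local: mean efficiency of each node's
neighbour-induced subgraph, nodes with < 2 neighbours contributing 0),
computed with networkx and validated against a Floyd–Warshall oracle.
Louvain module detection runs on the weighted graph after removing edges
below 0.5, with the resolution-γ (Reichardt–Bornholdt) quality function,
seed-shuffled node order, and module labels ordered by smallest member for
determinism. Isolated nodes become singletons.

A sample-level activity filter (`is_active_sample`) marks a recording
active when ≥ 10 % of sources have at least one significant onset; the
fraction is configurable since no principled value is established. The
variance captured by the first principal component is exposed as a
pass-through summary statistic (`first_pc_variance`).

**Phase boundaries.** The global-synchrony-vs-DIV profile is peak-located
and the boundaries are the first half-peak crossings on either side, linear
between DIV points; a side that never drops below half-peak is reported
open. An optional 3-point moving average is available but off by default —
with sparse DIV sampling (the worked 3-point example) smoothing destroys
the peak structure it is meant to stabilize.

## Multiresolution consensus

The informative resolution range is found by bisection: γ_min is the
largest γ at which Louvain returns one module (0 for disconnected graphs,
which never merge), γ_max the smallest γ giving all singletons. γ is
sampled uniformly on [γ_min, γ_max] with one refinement pass that
re-allocates half the samples to sub-intervals where the module count
changes fastest — an approximation to full partition-event sampling, which
is out of scope. Default 10,000 samples; tests and the acceptance script
use 150–500 (scaled down; the co-classification fractions they assert are
coarse enough that resolution error at 500 samples is negligible).
Co-classification P_ij is the fraction of ensemble partitions placing i and
j together; the consensus dendrogram is average-linkage on 1 − P with
internal nodes annotated by consensus probability, serialized as Newick.
The flat consensus partition cuts where mean within-cluster P ≥ 0.5. The
ensemble is built on the binary graph at cutoff 0.7, matching the
convention of the source analysis pipeline this re-implements.

## Treatment comparison

Matched before/after recordings are paired either directly (same extracted
source set) or by splitting a concatenated recording at the known segment
boundary. Edge weights for stability are the *raw* (unthresholded)
correlations so weak edges inform the fit; sources masked in either
condition are dropped from both. Stability is Pearson r of matched weights
per stratum (local/global) plus the R² of an ordinary least-squares fit of
after on before (with intercept, so R² = r² and is clipped to [0, 1]; the
direction of the fit is part of the definition). Δ-metrics are after −
before on the same sample for synchrony means, efficiencies (threshold
0.8) and activity rate.

The simulated rescue experiment records a baseline at normal coupling,
lowers ρ (the treatment), and either restores it before the
after-recording (rescue) or not (control). Rescue shows higher global
edge-weight stability in ≥ 90 % of seeds under the validation conditions:
`lambda_decay = 250 µm` and 0.2 events/s over 120 s. The shorter decay
length is essential to the statistic, not a tuning convenience — stability
correlates *pair-resolved* weight structure across conditions, and with
near-uniform coupling (the 1500 µm default over a 600 µm field) there is
almost no reproducible across-pair variance for it to detect.

## Registration

Translation-only alignment by exhaustive integer grid search (default
± 20 px) maximizing histogram-based mutual information (32 equal-width
bins on the overlapping region), with optional parabolic sub-pixel
refinement (off by default so planted integer shifts are recovered
exactly). The convention: the returned (dx, dy) is the shift that maps the
reference onto the moving image, so registering in the opposite direction
negates it. Grid search is deterministic and testable; no general-purpose
optimizer is involved. Rotation and non-rigid motion are out of scope.

## Gene-set overlap

The bootstrap draws `n_boot` (default 10⁶) sets of the query's size
uniformly *without replacement* from the universe (a random gene set cannot
repeat genes) and reports the fraction of draws whose overlap with the
target set is ≥ (and ≤) the observed overlap. Zero counts are reported as
an upper bound of 1/n_boot, the convention behind quoting P = 10⁻⁶ at 10⁶
draws. The exact hypergeometric tail is always computed alongside as a
cross-check; the bootstrap is retained because its resolution is what is
conventionally reported. Identifiers are case-normalized and
whitespace-stripped; in-list duplicates and genes outside the universe are
errors.

## What the synthetic validation shows — and does not

Passing tests demonstrate that every stage computes its defined quantity
correctly (oracle agreement, planted-structure recovery) and that the full
pipeline reproduces the qualitative biology the simulator encodes:
local ≫ global synchrony, distance decay, phase ordering, the mutant
direction, hierarchy recovery, and rescue-vs-control stability. They do not
validate performance on real movies — CNMF-style per-neuron source
separation, motion artefacts, indicator nonlinearity, amplitude
heterogeneity and multi-hop cascades are all outside the generative model.
The segmentation stage consumes aggregated spheroid-level signals;
per-neuron footprint extraction from overlapping somata is explicitly not
implemented.

## Problem sizes

Default simulated recordings are 9 spheroids × 6 neurons for 120 s at
30 Hz (3600 frames). The test suite and acceptance script use 8–20 seeds
per directional claim, 150–500 γ samples per consensus ensemble, and 10⁵
bootstrap draws per overlap estimate; these sizes keep each claim's
sampling error well below the asserted margins.
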