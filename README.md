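# monnet

Analysis pipeline for calcium imaging of **modular neuronal networks
(MoNNets)** — self-organized 3D cultures of interconnected neuronal
spheroids — together with a synthetic simulator that generates recordings
with known ground truth so every stage of the analysis can be validated
end to end.

It is aimed at labs quantifying ensemble synchrony in spheroid/organoid
cultures: how tightly neurons inside one spheroid fire together (*local*
synchrony), how strongly activity couples across spheroids (*global*
synchrony), how that coupling organizes into network modules, and how all
of this changes with culture age, genotype, or pharmacology.

## What it computes

Given a fluorescence movie (or pre-extracted traces) the pipeline produces:

- **Segmentation & traces** — watershed segmentation of spheroid units on the
  maximum-intensity projection; frame-wise background subtraction (mean
  intensity outside the total mask); per-label aggregated signals;
  morphometrics (sizes, nearest-neighbour centre distances).
- **∂F/F and activity onsets** — baseline = 8th percentile in a sliding
  500-frame window; ∂F/F = (F − F₀)/F₀; median denoising; nonnegative
  deconvolution under a second-order autoregressive calcium model
  c_t = g₁·c_{t−1} + g₂·c_{t−2} + s_t; events = onsets above 5 robust SD;
  activity rate (events/min) and clustered activity duration (full width at
  75% or 50% of the ∂F/F peak).
- **Functional graphs** — Pearson correlation of ∂F/F for all source pairs;
  local/global/overall mean synchrony split by spheroid membership;
  correlation vs. physical distance; global and local efficiency of the
  graph binarized at r ≥ 0.8; Louvain modules on the weighted graph with
  edges below 0.5 removed.
- **Multiresolution consensus** — Louvain partitions sampled across the whole
  informative range of the Reichardt–Bornholdt resolution γ (10,000 samples
  by default), pairwise co-classification probabilities, and an
  average-linkage consensus dendrogram (the binary graph uses an edge cutoff
  of 0.7).
- **Treatment comparison** — matched before/after recordings: Δ-metrics
  (after − before) for synchrony, efficiency and rate, and edge-weight
  stability (Pearson r and R² of the after-on-before fit) split into local
  and global strata.
- **Gene-set overlap** — a bootstrap test (default 10⁶ draws) of whether a
  query gene set overlaps a target set more (or less) than uniform random
  sets drawn from the expressed-gene universe, with the exact
  hypergeometric tail reported alongside.

The simulator (`monnet.simulate`) generates spheroid layouts, modular
Poisson event trains with distance-decaying inter-spheroid propagation,
AR(2) calcium fluorescence, rendered movies, and gene-set fixtures with a
planted overlap. A coupling factor ρ emulates genotype: ρ = 1 is
wild-type-like; ρ < 1 weakens global coupling the way mutant cultures show
reduced global synchrony with intact local synchrony.

## Worked example

```python
import numpy as np
from monnet import simulate as sim, traces, network

cfg = sim.phase_preset("wt", seed=1)          # 9 spheroids x 6 neurons, 120 s at 30 Hz
layout = sim.generate_layout(cfg)
spikes, F = sim.simulate_activity(layout, cfg)

dff = traces.compute_dff(traces.FluorescenceMatrix(F, cfg.frame_rate))
G = network.pairwise_correlation(dff, membership=layout.membership)
summary = network.local_global_summary(G)
eg, el = network.graph_efficiency(network.binarize(G, 0.8))
part = network.detect_modules(G, threshold=0.5, seed=1)

print(f"local r  = {summary['local']:.3f}")
print(f"global r = {summary['global']:.3f}")
print(f"E_glob   = {eg:.3f}, modules = {part.n_modules}")
```

Output:

```
local r  = 0.908
global r = 0.746
E_glob   = 0.589, modules = 4
```

Neurons within one spheroid are almost perfectly synchronized (local
r ≈ 0.91); in this synchronized, wild-type-like regime activity also couples
strongly across spheroids (global r ≈ 0.75), giving a well-connected
functional graph (global efficiency 0.59 at the 0.8 edge threshold) with a
few large modules. Re-running with `sim.phase_preset("mutant", seed=1)`
(ρ = 0.2) leaves local r essentially unchanged but collapses global
synchrony, efficiency drops to the within-spheroid floor, and the module
count rises towards one module per spheroid.

The same stages are available from the shell:

```bash
monnet simulate --preset wt --seed 1 --out-dir run/
monnet traces  --in run/traces.csv --out-dir run/
monnet network --dff run/dff.csv --membership run/membership.csv --out-dir run/
```

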