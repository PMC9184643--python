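"""Functional connectivity graphs and ensemble synchrony statistics.

Pairwise Pearson correlation of dF/F traces defines a weighted functional
graph over sources.  Binary graphs thresholded at 0.8 feed global/local
efficiency; Louvain modules are detected on the weighted graph after removing
edges below 0.5.  Local vs global synchrony splits pairs by spheroid
membership; the three-phase synchrony trajectory over days in vitro is
summarized by half-peak phase boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .traces import DffMatrix, OnsetMatrix, significant_onset_mask

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationGraph",
    "BinaryGraph",
    "ModulePartition",
    "PhaseProfile",
    "pairwise_correlation",
    "local_global_summary",
    "correlation_vs_distance",
    "binarize",
    "graph_efficiency",
    "detect_modules",
    "estimate_phase_boundaries",
    "is_active_sample",
    "first_pc_variance",
]


@dataclass
class CorrelationGraph:
    """Symmetric Pearson-correlation matrix with membership annotations.

    Entries involving constant traces are undefined and masked out
    (``valid`` False); such nodes are excluded from every derived graph.
    """

    C: np.ndarray
    membership: np.ndarray | None = None
    positions: np.ndarray | None = None  # (n, 2) um, optional
    valid: np.ndarray | None = None  # per-node mask

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        n = self.C.shape[0]
        if self.C.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if self.valid is None:
            self.valid = ~np.isnan(self.C).all(axis=1)
        if self.membership is not None:
            self.membership = np.asarray(self.membership, int)
            if len(self.membership) != n:
                raise ValueError("membership length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    def defined(self) -> np.ndarray:
        """Boolean mask of defined (unmasked) off-diagonal entries."""
        ok = np.outer(self.valid, self.valid) & ~np.isnan(self.C)
        np.fill_diagonal(ok, False)
        return ok


@dataclass
class BinaryGraph:
    """Undirected adjacency from thresholding edge weights (r >= threshold)."""

    adjacency: np.ndarray
    threshold: float
    nodes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, bool)
        if not np.array_equal(A, A.T) or A.diagonal().any():
            raise ValueError("adjacency must be symmetric with no self-loops")
        self.adjacency = A
        if self.nodes is None:
            self.nodes = np.arange(A.shape[0])

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency.astype(int))
        return nx.relabel_nodes(G, dict(enumerate(self.nodes)))


@dataclass
class ModulePartition:
    """Node-to-module assignment with modularity quality."""

    labels: np.ndarray
    modularity: float
    resolution: float
    seed: int
    nodes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        # relabel consecutively from 0 in order of first appearance
        _, self.labels = np.unique(self.labels, return_inverse=True)
        if self.nodes is None:
            self.nodes = np.arange(len(self.labels))

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class PhaseProfile:
    """Mean global pairwise correlation as a function of days in vitro."""

    div: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.div = np.asarray(self.div, float)
        self.correlation = np.asarray(self.correlation, float)
        if len(self.div) != len(self.correlation):
            raise ValueError("div and correlation lengths differ")
        if np.any(np.diff(self.div) <= 0):
            raise ValueError("div must be strictly increasing")


def pairwise_correlation(
    dff: np.ndarray | DffMatrix,
    membership: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> CorrelationGraph:
    """Pearson correlation of dF/F traces for all source pairs.

    Constant traces (zero variance) and flagged sources are masked: their
    rows/columns are NaN and they are excluded from derived graphs.
    """
    pre_valid = None
    if isinstance(dff, DffMatrix):
        pre_valid = dff.valid.copy()
        arr = dff.dff
    else:
        arr = np.atleast_2d(np.asarray(dff, float))
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 sources")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    sd = np.nanstd(arr, axis=1)
    valid = (sd > 0) & np.isfinite(arr).all(axis=1)
    if pre_valid is not None:
        valid &= pre_valid
    n = arr.shape[0]
    C = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        C_sub = np.corrcoef(arr[valid])
        ix = np.flatnonzero(valid)
        C[np.ix_(ix, ix)] = C_sub
    C[np.flatnonzero(valid), np.flatnonzero(valid)] = 1.0
    n_masked = int((~valid).sum())
    if n_masked:
        logger.info("masked %d constant/invalid source(s)", n_masked)
    return CorrelationGraph(C, membership=membership, positions=positions,
                            valid=valid)


def local_global_summary(G: CorrelationGraph) -> dict:
    """Mean pairwise correlation split by spheroid membership.

    ``local`` averages within-spheroid pairs, ``global`` across-spheroid
    pairs, ``overall`` all pairs; masked entries are excluded.  With a single
    spheroid the global mean is reported as NaN (missing), not 0.
    """
    if G.membership is None:
        raise ValueError("membership required")
    ok = G.defined()
    same = G.membership[:, None] == G.membership[None, :]
    iu = np.triu(np.ones_like(ok, dtype=bool), k=1)
    local_mask = ok & same & iu
    global_mask = ok & ~same & iu
    all_mask = ok & iu
    out = {
        "local": float(G.C[local_mask].mean()) if local_mask.any() else float("nan"),
        "global": float(G.C[global_mask].mean()) if global_mask.any() else float("nan"),
        "overall": float(G.C[all_mask].mean()) if all_mask.any() else float("nan"),
        "n_local_pairs": int(local_mask.sum()),
        "n_global_pairs": int(global_mask.sum()),
    }
    if len(np.unique(G.membership[G.valid])) < 2:
        out["global"] = float("nan")
    return out


def correlation_vs_distance(
    G: CorrelationGraph,
    positions: np.ndarray | None = None,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Across-spheroid correlation binned by physical pair distance.

    Distances are Euclidean between source positions (um); bins are
    ``[k*bin_width, (k+1)*bin_width)``.  Returns columns distance (bin
    centre), mean_r, n_pairs.
    """
    pos = positions if positions is not None else G.positions
    if pos is None:
        raise ValueError("positions required")
    if G.membership is None:
        raise ValueError("membership required")
    pos = np.asarray(pos, float)
    ok = G.defined()
    same = G.membership[:, None] == G.membership[None, :]
    iu = np.triu(np.ones_like(ok, dtype=bool), k=1)
    mask = ok & ~same & iu
    if not mask.any():
        return pd.DataFrame(columns=["distance", "mean_r", "n_pairs"])
    i, j = np.nonzero(mask)
    d = np.hypot(*(pos[i] - pos[j]).T)
    r = G.C[i, j]
    bins = (d // bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append({"distance": (b + 0.5) * bin_width,
                     "mean_r": float(r[sel].mean()),
                     "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows)


def binarize(G: CorrelationGraph, threshold: float = 0.8) -> BinaryGraph:
    """Binary graph: edge iff r >= threshold (masked entries never edge).

    Masked (invalid) nodes are excluded from the graph entirely.
    """
    if not -1.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (-1, 1]")
    ix = np.flatnonzero(G.valid)
    C = G.C[np.ix_(ix, ix)]
    with np.errstate(invalid="ignore"):
        A = np.nan_to_num(C, nan=-np.inf) >= threshold
    np.fill_diagonal(A, False)
    A = A & A.T
    return BinaryGraph(A, threshold, nodes=ix)


def graph_efficiency(B: BinaryGraph) -> tuple[float, float]:
    """Global and local efficiency of a binary graph.

    Global efficiency is the mean over ordered node pairs of the inverse
    shortest-path length (0 for disconnected pairs); local efficiency is the
    mean over nodes of the global efficiency of the subgraph induced on each
    node's neighbours (< 2 neighbours contributes 0).
    """
    n = B.adjacency.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    G = nx.from_numpy_array(B.adjacency.astype(int))
    return float(nx.global_efficiency(G)), float(nx.local_efficiency(G))


def detect_modules(
    G: CorrelationGraph | np.ndarray,
    threshold: float = 0.5,
    resolution: float = 1.0,
    seed: int = 0,
) -> ModulePartition:
    """Louvain community detection on the thresholded weighted graph.

    Edges with weight below ``threshold`` are removed before greedy
    modularity optimization (node-move + aggregation phases, node visit order
    shuffled by ``seed``); isolated nodes become singleton modules.  The
    positive thresholds in routine use mean negative correlations never enter
    the graph.
    """
    if isinstance(G, CorrelationGraph):
        ix = np.flatnonzero(G.valid)
        W = np.nan_to_num(G.C[np.ix_(ix, ix)], nan=-np.inf)
    else:
        W = np.asarray(G, float)
        ix = np.arange(W.shape[0])
    n = W.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(W >= threshold, k=1))
    g.add_weighted_edges_from(zip(i.tolist(), j.tolist(), W[i, j].tolist()))
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    labels = np.empty(n, dtype=int)
    # deterministic module order: by smallest member node
    for m, comm in enumerate(sorted(comms, key=min)):
        labels[list(comm)] = m
    if g.number_of_edges() > 0:
        q = float(nx.community.modularity(
            g, [set(np.flatnonzero(labels == m)) for m in np.unique(labels)],
            weight="weight", resolution=resolution,
        ))
    else:
        q = 0.0
    return ModulePartition(labels, q, resolution, seed, nodes=ix)


def estimate_phase_boundaries(
    profile: PhaseProfile, smooth: bool = False
) -> tuple[float | None, float | None]:
    """Half-peak boundaries of the global-synchrony trajectory.

    Locates the profile peak and returns the DIV of the first half-peak
    crossing before and after it, linearly interpolated between DIV points.
    A side where the profile never drops below half-peak is reported as None
    with a warning.  ``smooth=True`` applies a 3-point moving average first.
    """
    if len(profile.div) < 3:
        raise ValueError("need at least 3 DIV points")
    y = profile.correlation.astype(float)
    if smooth and len(y) >= 3:
        y = np.convolve(y, np.ones(3) / 3, mode="same")
        y[0] = profile.correlation[:2].mean()
        y[-1] = profile.correlation[-2:].mean()
    x = profile.div
    if np.ptp(y) == 0:
        raise ValueError("flat profile has no peak structure")
    p = int(np.argmax(y))
    half = y[p] / 2.0

    def cross(indices, after):
        # walk away from the peak; find first segment crossing `half`
        prev = p
        for k in indices:
            if y[k] < half:
                x0, y0 = x[prev], y[prev]
                x1, y1 = x[k], y[k]
                if y1 == y0:
                    return float(x1)
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            prev = k
        warnings.warn("profile never drops below half-peak on the "
                      + ("upper" if after else "lower") + " side; boundary open")
        return None

    low = cross(range(p - 1, -1, -1), after=False)
    high = cross(range(p + 1, len(y)), after=True)
    return low, high


def is_active_sample(
    onsets: OnsetMatrix, min_fraction: float = 0.1, sd_thresh: float = 5.0
) -> bool:
    """Sample-level activity filter: >= ``min_fraction`` of sources must have
    at least one significant onset."""
    sig = significant_onset_mask(onsets, sd_thresh)
    frac = (sig.any(axis=1)).mean()
    return bool(frac >= min_fraction)


def first_pc_variance(dff: np.ndarray | DffMatrix) -> float:
    """Fraction of activity variance captured by the first principal component."""
    arr = dff.dff if isinstance(dff, DffMatrix) else np.atleast_2d(np.asarray(dff, float))
    arr = arr[np.isfinite(arr).all(axis=1)]
    arr = arr - arr.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(arr, compute_uv=False)
    tot = np.sum(svals**2)
    return float(svals[0] ** 2 / tot) if tot > 0 else float("nan")
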