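"""Multiresolution modularity ensembles and hierarchical consensus clustering.

Community structure at a single resolution is scale-biased, so the graph is
partitioned across the whole informative range of the Reichardt-Bornholdt
resolution parameter gamma: from the largest gamma that still yields a single
module up to the smallest gamma that shatters the graph into singletons.
Co-classification probabilities (the fraction of ensemble partitions placing
two nodes in the same module) summarize the ensemble, and average-linkage
clustering of 1 - P yields the hierarchical consensus dendrogram.

Following the source analysis convention, the ensemble is built on the binary
graph obtained with an edge-weight cutoff of 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .network import BinaryGraph, CorrelationGraph, ModulePartition, binarize, detect_modules

__all__ = [
    "PartitionEnsemble",
    "CoClassification",
    "gamma_range",
    "multiresolution_ensemble",
    "coclassification_matrix",
    "hierarchical_consensus",
    "consensus_partition",
]


@dataclass
class PartitionEnsemble:
    """Louvain partitions sampled across modularity resolutions."""

    partitions: list[ModulePartition]
    gammas: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, float)
        if len(self.partitions) != len(self.gammas):
            raise ValueError("one gamma per partition required")
        n_nodes = {len(p.labels) for p in self.partitions}
        if len(n_nodes) > 1:
            raise ValueError("all partitions must cover the same node set")

    @property
    def n_samples(self) -> int:
        return len(self.partitions)

    def label_matrix(self) -> np.ndarray:
        return np.stack([p.labels for p in self.partitions])


@dataclass
class CoClassification:
    """Co-classification probability matrix and its consensus dendrogram."""

    P: np.ndarray
    linkage: np.ndarray | None = None  # scipy linkage matrix on 1 - P

    def __post_init__(self) -> None:
        P = np.asarray(self.P, float)
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("P must be symmetric")
        if P.min() < -1e-12 or P.max() > 1 + 1e-12:
            raise ValueError("P entries must lie in [0, 1]")
        self.P = np.clip(P, 0.0, 1.0)
        np.fill_diagonal(self.P, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.P.shape[0]


def _partition_at(adj: np.ndarray, gamma: float, seed: int) -> ModulePartition:
    return detect_modules(adj.astype(float), threshold=0.5, resolution=gamma,
                          seed=seed)


def gamma_range(
    adj: np.ndarray, seed: int = 0, tol: float = 1e-3, max_gamma: float = 1e6
) -> tuple[float, float]:
    """Informative resolution range [gamma_min, gamma_max].

    gamma_min is the largest gamma (found by bisection) at which Louvain
    returns a single module, or 0 if the graph is never merged into one
    (e.g. disconnected graphs).  gamma_max is the smallest gamma at which
    every node is a singleton.
    """
    n = adj.shape[0]

    def n_modules(g: float) -> int:
        return _partition_at(adj, g, seed).n_modules

    # gamma_min: bisect on [0, hi] for the 1-module/multi-module transition
    if n_modules(0.0) > 1:
        g_min = 0.0
    else:
        lo, hi = 0.0, 1.0
        while n_modules(hi) == 1 and hi < max_gamma:
            lo, hi = hi, hi * 2
        while hi - lo > tol * max(1.0, lo):
            mid = 0.5 * (lo + hi)
            if n_modules(mid) == 1:
                lo = mid
            else:
                hi = mid
        g_min = lo
    # gamma_max: bisect for the all-singletons transition
    lo, hi = max(g_min, 1.0), 2.0
    while n_modules(hi) < n and hi < max_gamma:
        lo, hi = hi, hi * 2
    if n_modules(hi) < n:
        return g_min, hi  # never shatters (no edges case handled upstream)
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if n_modules(mid) < n:
            lo = mid
        else:
            hi = mid
    return g_min, hi


def multiresolution_ensemble(
    G: CorrelationGraph | BinaryGraph | np.ndarray,
    threshold: float = 0.7,
    n_samples: int = 10_000,
    seed: int = 0,
    refine: bool = True,
) -> PartitionEnsemble:
    """Partition ensemble across uniformly sampled modularity resolutions.

    The correlation graph is binarized at ``threshold`` (default 0.7); gamma
    is sampled uniformly on [gamma_min, gamma_max] with one refinement pass
    that re-samples the sub-intervals where the module count changes fastest,
    approximating uniform coverage of partition events.  One seeded Louvain
    partition is drawn per gamma.  An edgeless graph yields all-singleton
    partitions with a warning.
    """
    if isinstance(G, CorrelationGraph):
        B = binarize(G, threshold)
        adj = B.adjacency
    elif isinstance(G, BinaryGraph):
        adj = G.adjacency
    else:
        adj = np.asarray(G) != 0
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes after thresholding")
    rng = np.random.default_rng(seed)
    if not adj.any():
        warnings.warn("graph has no edges; ensemble is all singletons")
        gammas = np.ones(n_samples)
        parts = [ModulePartition(np.arange(n), 0.0, 1.0, seed)
                 for _ in range(n_samples)]
        return PartitionEnsemble(parts, gammas, seed)
    g_min, g_max = gamma_range(adj, seed=seed)
    n_first = n_samples if not refine else max(n_samples // 2, 1)
    gammas = np.sort(rng.uniform(g_min, g_max, size=n_first))
    parts = [_partition_at(adj, g, int(rng.integers(2**31))) for g in gammas]
    if refine and n_samples - n_first > 0:
        counts = np.array([p.n_modules for p in parts])
        change = np.abs(np.diff(counts)).astype(float)
        if change.sum() == 0:
            change[:] = 1.0
        w = change / change.sum()
        extra_per_gap = rng.multinomial(n_samples - n_first, w)
        g2 = []
        for k, m in enumerate(extra_per_gap):
            if m:
                g2.extend(rng.uniform(gammas[k], gammas[k + 1], size=m))
        g2 = np.asarray(g2)
        parts += [_partition_at(adj, g, int(rng.integers(2**31))) for g in g2]
        gammas = np.concatenate([gammas, g2])
    order = np.argsort(gammas)
    parts = [parts[k] for k in order]
    return PartitionEnsemble(parts, gammas[order], seed)


def coclassification_matrix(ensemble: PartitionEnsemble) -> CoClassification:
    """P_ij = fraction of ensemble partitions placing i and j in one module."""
    if ensemble.n_samples == 0:
        raise ValueError("empty ensemble")
    L = ensemble.label_matrix()  # samples x nodes
    n = L.shape[1]
    P = np.zeros((n, n))
    for labels in L:
        P += labels[:, None] == labels[None, :]
    P /= len(L)
    return CoClassification(P)


def hierarchical_consensus(
    cc: CoClassification | np.ndarray, alpha: float = 0.05
) -> CoClassification:
    """Average-linkage consensus dendrogram on dissimilarity 1 - P.

    Returns the CoClassification with its ``linkage`` field populated
    (scipy format); internal-node heights are 1 minus the mean
    co-classification probability merged at that node.
    """
    cc = cc if isinstance(cc, CoClassification) else CoClassification(np.asarray(cc))
    D = 1.0 - cc.P
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return CoClassification(cc.P, linkage=Z)


def consensus_partition(cc: CoClassification, min_p: float = 0.5) -> np.ndarray:
    """Flat consensus modules: cut the dendrogram where mean P >= ``min_p``."""
    if cc.linkage is None:
        cc = hierarchical_consensus(cc)
    flat = hierarchy.fcluster(cc.linkage, t=1.0 - min_p, criterion="distance")
    _, labels = np.unique(flat, return_inverse=True)
    return labels


def to_newick(cc: CoClassification, leaf_names: list[str] | None = None) -> str:
    """Serialize the consensus dendrogram as Newick.

    Internal-node labels carry the consensus probability (1 - merge height);
    branch lengths are height differences.
    """
    if cc.linkage is None:
        cc = hierarchical_consensus(cc)
    Z = cc.linkage
    n = cc.n_nodes
    names = leaf_names or [str(i) for i in range(n)]

    heights = np.concatenate([np.zeros(n), Z[:, 2]])

    def node(idx: int, parent_h: float) -> str:
        bl = max(parent_h - heights[idx], 0.0)
        if idx < n:
            return f"{names[idx]}:{bl:.6g}"
        row = Z[idx - n]
        children = ",".join(node(int(c), heights[idx]) for c in row[:2])
        p = 1.0 - heights[idx]
        return f"({children}){p:.4g}:{bl:.6g}"

    root = 2 * n - 2
    return node(root, heights[root]) + ";"
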