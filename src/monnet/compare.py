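"""Before/after-treatment comparison of matched samples.

Treatment effects are quantified within-sample: the same sources are tracked
across the two recordings (source extraction runs on the registered,
concatenated stacks, so identity is by construction), and every metric is
reported as a delta (after - before).  Edge-weight stability is the Pearson
correlation (and the R^2 of an ordinary least-squares straight-line fit of
after on before) between matched pairwise-correlation edge weights, split
into within-spheroid (local) and across-spheroid (global) strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import binarize, graph_efficiency, local_global_summary, pairwise_correlation
from .traces import DffMatrix, activity_rate, infer_onsets

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentPair",
    "StabilityResult",
    "DeltaMetrics",
    "pair_conditions",
    "split_concatenated",
    "edge_stability",
    "delta_metrics",
]


@dataclass
class TreatmentPair:
    """Matched before/after dF/F matrices over an identical source set."""

    before: DffMatrix
    after: DffMatrix
    membership: np.ndarray | None = None
    translation: tuple[float, float] | None = None  # (dx, dy) px applied

    def __post_init__(self) -> None:
        if self.before.n_sources != self.after.n_sources:
            raise ValueError("before/after source counts differ")
        if list(self.before.source_ids) != list(self.after.source_ids):
            raise ValueError("before/after source identities differ")
        if self.before.frame_rate != self.after.frame_rate:
            raise ValueError("before/after frame rates differ")
        if self.membership is not None:
            self.membership = np.asarray(self.membership, int)
            if len(self.membership) != self.before.n_sources:
                raise ValueError("membership length mismatch")


@dataclass
class StabilityResult:
    """Edge-weight stability statistics per membership stratum."""

    pcc_local: float
    pcc_global: float
    rsq_local: float
    rsq_global: float
    n_local: int
    n_global: int
    scatter: pd.DataFrame | None = None  # pair_id, stratum, w_before, w_after


@dataclass
class DeltaMetrics:
    """after - before deltas of the sample-level synchrony metrics."""

    d_local: float
    d_global: float
    d_overall: float
    d_global_efficiency: float
    d_local_efficiency: float
    d_rate: float


def pair_conditions(
    before: DffMatrix, after: DffMatrix,
    membership: np.ndarray | None = None,
    translation: tuple[float, float] | None = None,
) -> TreatmentPair:
    """Pair two per-condition dF/F matrices extracted over the same sources."""
    return TreatmentPair(before, after, membership, translation)


def split_concatenated(
    dff: DffMatrix, n_before: int,
    membership: np.ndarray | None = None,
    translation: tuple[float, float] | None = None,
) -> TreatmentPair:
    """Split a concatenated-recording dF/F matrix back into before/after.

    ``n_before`` is the frame count of the before segment; an inconsistent
    count is an error.  The identity mapping between conditions is trivial
    because the sources were extracted jointly.
    """
    if not 0 < n_before < dff.n_frames:
        raise ValueError(
            f"n_before={n_before} inconsistent with {dff.n_frames} total frames"
        )
    mk = lambda arr, base: DffMatrix(
        arr, base, dff.frame_rate, dff.window, dff.percentile,
        dff.source_ids, dff.valid.copy(),
    )
    before = mk(dff.dff[:, :n_before], dff.baseline[:, :n_before])
    after = mk(dff.dff[:, n_before:], dff.baseline[:, n_before:])
    return TreatmentPair(before, after, membership, translation)


def _stratum_stats(wb: np.ndarray, wa: np.ndarray) -> tuple[float, float, int]:
    n = len(wb)
    if n < 2 or np.std(wb) == 0 or np.std(wa) == 0:
        return float("nan"), float("nan"), n
    r = float(stats.pearsonr(wb, wa).statistic)
    # OLS of after on before with intercept: R^2 = r^2, clipped to [0, 1]
    rsq = float(np.clip(r * r, 0.0, 1.0))
    return r, rsq, n


def edge_stability(
    pair: TreatmentPair, membership: np.ndarray | None = None,
    keep_scatter: bool = True,
) -> StabilityResult:
    """Correlation of matched raw edge weights before vs after treatment.

    Edge weights are the unthresholded Pearson correlations of the dF/F
    traces within each condition.  Sources masked in either condition are
    dropped from both (pairwise-complete policy).
    """
    mem = membership if membership is not None else pair.membership
    if mem is None:
        raise ValueError("membership required")
    mem = np.asarray(mem, int)
    Gb = pairwise_correlation(pair.before, membership=mem)
    Ga = pairwise_correlation(pair.after, membership=mem)
    keep = Gb.valid & Ga.valid
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d source(s) masked in either condition", n_drop)
    ok = Gb.defined() & Ga.defined() & np.outer(keep, keep)
    iu = np.triu(np.ones_like(ok, dtype=bool), k=1)
    same = mem[:, None] == mem[None, :]
    rows = []
    res = {}
    for stratum, mask in (("local", ok & same & iu), ("global", ok & ~same & iu)):
        i, j = np.nonzero(mask)
        wb, wa = Gb.C[i, j], Ga.C[i, j]
        r, rsq, n = _stratum_stats(wb, wa)
        res[stratum] = (r, rsq, n)
        if keep_scatter:
            rows.extend(
                {"pair_id": f"{a}-{b}", "stratum": stratum,
                 "w_before": float(x), "w_after": float(y)}
                for a, b, x, y in zip(i, j, wb, wa)
            )
    scatter = pd.DataFrame(rows) if keep_scatter else None
    return StabilityResult(
        pcc_local=res["local"][0], pcc_global=res["global"][0],
        rsq_local=res["local"][1], rsq_global=res["global"][1],
        n_local=res["local"][2], n_global=res["global"][2],
        scatter=scatter,
    )


def _condition_metrics(dff: DffMatrix, mem: np.ndarray,
                       efficiency_threshold: float, g1, g2) -> dict:
    G = pairwise_correlation(dff, membership=mem)
    summ = local_global_summary(G)
    eg, el = graph_efficiency(binarize(G, efficiency_threshold))
    onsets = infer_onsets(dff, g1, g2)
    _, rate = activity_rate(onsets)
    return {"local": summ["local"], "global": summ["global"],
            "overall": summ["overall"], "eg": eg, "el": el, "rate": rate}


def delta_metrics(
    pair: TreatmentPair, membership: np.ndarray | None = None,
    efficiency_threshold: float = 0.8,
    g1: float | None = None, g2: float | None = None,
) -> DeltaMetrics:
    """after - before deltas of synchrony, efficiency and activity rate."""
    mem = membership if membership is not None else pair.membership
    if mem is None:
        raise ValueError("membership required")
    b = _condition_metrics(pair.before, mem, efficiency_threshold, g1, g2)
    a = _condition_metrics(pair.after, mem, efficiency_threshold, g1, g2)
    return DeltaMetrics(
        d_local=a["local"] - b["local"],
        d_global=a["global"] - b["global"],
        d_overall=a["overall"] - b["overall"],
        d_global_efficiency=a["eg"] - b["eg"],
        d_local_efficiency=a["el"] - b["el"],
        d_rate=a["rate"] - b["rate"],
    )
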