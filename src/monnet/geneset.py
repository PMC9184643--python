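"""Bootstrap gene-set overlap test.

Estimates the probability that the observed overlap between a query gene set
(e.g. differentially expressed genes) and a target set (e.g. ChIP-seq
targets) arises by chance, by drawing many random sets of the query's size
uniformly without replacement from the expressed-gene universe.  The exact
hypergeometric tail is always computed alongside as a cross-check; the
bootstrap estimate is retained because its resolution (1/n_boot) is the
quantity conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OverlapResult", "bootstrap_overlap", "read_gene_list"]


@dataclass
class OverlapResult:
    """Observed overlap with bootstrap and exact tail probabilities.

    ``p_ge`` / ``p_le`` are the bootstrap fractions of draws with overlap
    >= / <= the observed count.  A zero count cannot be distinguished from
    p < 1/n_boot, so it is reported as 1/n_boot with ``p_ge_is_upper_bound``
    set (mirroring the convention of quoting P = 1e-6 at 10^6 draws).
    """

    observed_k: int
    p_ge: float
    p_le: float
    n_boot: int
    seed: int
    analytic_p_ge: float
    analytic_p_le: float
    p_ge_is_upper_bound: bool = False
    p_le_is_upper_bound: bool = False

    def summary(self) -> str:
        ge = f"< {1 / self.n_boot:g}" if self.p_ge_is_upper_bound else f"{self.p_ge:g}"
        le = f"< {1 / self.n_boot:g}" if self.p_le_is_upper_bound else f"{self.p_le:g}"
        return (
            f"overlap k = {self.observed_k}\n"
            f"P[overlap >= k] = {ge} (bootstrap, {self.n_boot} draws); "
            f"exact {self.analytic_p_ge:.3g}\n"
            f"P[overlap <= k] = {le} (bootstrap); exact {self.analytic_p_le:.3g}"
        )


def _normalize(genes, name: str) -> list[str]:
    out = [str(g).strip().upper() for g in genes]
    out = [g for g in out if g]
    if len(set(out)) != len(out):
        dups = sorted({g for g in out if out.count(g) > 1})
        raise ValueError(f"duplicate gene identifiers in {name}: {dups[:5]}")
    return out


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; normalized and deduplicated-checked."""
    with open(path) as fh:
        return _normalize([line for line in fh if line.strip()], str(path))


def bootstrap_overlap(
    universe, targets, query, n_boot: int = 1_000_000, seed: int = 0
) -> OverlapResult:
    """Bootstrap the null distribution of |targets ∩ random set of |query||.

    Draws ``n_boot`` sets of size |query| uniformly without replacement from
    the universe and compares their overlap with ``targets`` to the observed
    overlap.  Gene identifiers are case-normalized and whitespace-stripped;
    duplicates within a list are an error, as are genes outside the universe.
    """
    universe = _normalize(universe, "universe")
    targets = _normalize(targets, "targets")
    query = _normalize(query, "query")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    uni = set(universe)
    for name, s in (("targets", targets), ("query", query)):
        stray = sorted(set(s) - uni)
        if stray:
            raise ValueError(f"{name} not in universe: {stray[:5]}")
    N, K, n = len(universe), len(targets), len(query)
    target_mask = np.isin(np.array(universe), np.array(targets))
    observed_k = int(len(set(targets) & set(query)))

    rng = np.random.default_rng(seed)
    ge = le = 0
    chunk = max(1, min(n_boot, int(2e7 // max(N, 1))))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        # uniform random n-subsets via argpartition of random keys
        keys = rng.random((m, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        k_sim = target_mask[idx].sum(axis=1)
        ge += int((k_sim >= observed_k).sum())
        le += int((k_sim <= observed_k).sum())
        done += m

    analytic_ge = float(stats.hypergeom.sf(observed_k - 1, N, K, n))
    analytic_le = float(stats.hypergeom.cdf(observed_k, N, K, n))
    ge_bound = ge == 0
    le_bound = le == 0
    return OverlapResult(
        observed_k=observed_k,
        p_ge=(max(ge, 1) / n_boot) if ge_bound else ge / n_boot,
        p_le=(max(le, 1) / n_boot) if le_bound else le / n_boot,
        n_boot=n_boot,
        seed=seed,
        analytic_p_ge=analytic_ge,
        analytic_p_le=analytic_le,
        p_ge_is_upper_bound=ge_bound,
        p_le_is_upper_bound=le_bound,
    )
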