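"""Over-representation analysis (ORA) of network mRNAs against gene-set
collections.

This is a plain one-sided hypergeometric test per term with BH FDR across
terms — the canonical statistic behind pathway-enrichment bar charts.  No
annotation database is bundled: the caller supplies a GMT collection and a
gene universe (conventionally the expressed genes of the experiment, not
the whole genome).  Gene identifiers are matched by exact string after
case-folding; no symbol/accession mapping is attempted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from scipy import stats as sps
from scipy.special import logsumexp
import numpy as np

from .destats import bh_adjust
from .tabio import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_tail", "ora"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation statistics.

    k = |query ∩ set|, K = |set ∩ universe|, n = |query|, N = |universe|;
    fold_enrichment = (k/n) / (K/N).
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float
    fold_enrichment: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space over the support [k, min(K, n)] for numerical
    stability at extreme enrichments.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"infeasible hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def ora(query: Iterable[str], collection: GeneSetCollection,
        universe: Iterable[str]) -> list[EnrichmentResult]:
    """One-sided over-representation of ``query`` in each set of the collection.

    Genes are case-folded before matching.  Query genes outside the universe
    are pruned with a warning.  Terms whose set does not intersect the
    universe are skipped (K = 0 carries no information).  Results carry BH
    FDR across all tested terms and are sorted by (fdr, p, term).
    """
    universe_set = {g.casefold() for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    query_raw = {g.casefold() for g in query}
    pruned = query_raw - universe_set
    if pruned:
        warnings.warn(
            f"{len(pruned)} query gene(s) not in the universe were pruned",
            stacklevel=2)
    query_set = query_raw & universe_set

    N = len(universe_set)
    n = len(query_set)
    rows: list[tuple[str, int, int]] = []
    for term, members in collection.sets.items():
        members_cf = {m.casefold() for m in members}
        K = len(members_cf & universe_set)
        if K == 0:
            continue
        k = len(members_cf & query_set)
        rows.append((term, k, K))

    pvals = [hypergeom_tail(k, K, n, N) for _term, k, K in rows]
    fdrs = bh_adjust(pvals)
    results = []
    for (term, k, K), p, fdr in zip(rows, pvals, fdrs):
        fold = (k / n) / (K / N) if n > 0 and k > 0 else 0.0
        results.append(EnrichmentResult(term=term, k=k, K=K, n=n, N=N,
                                        p=p, fdr=fdr, fold_enrichment=fold))
    results.sort(key=lambda r: (r.fdr, r.p, r.term))
    return results
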