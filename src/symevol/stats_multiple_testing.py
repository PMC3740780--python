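"""Inference summary layer: LRT p-values, BH FDR, SGoF, GO enrichment.

The likelihood-ratio statistic 2(lnL1 - lnL0) is referred to chi-square with
one degree of freedom.  Two multiple-testing corrections are provided:
Benjamini-Hochberg step-up FDR (via statsmodels) and the sequential
goodness-of-fit (SGoF) procedure, which compares the observed count of
sub-alpha p-values against its Binomial(n, alpha) expectation with an exact
binomial metatest.  GO-term enrichment is an upper-tail hypergeometric test
over a flat gene -> term annotation map, BH-adjusted across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom, chi2, hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class PValueSet:
    ids: list[str]
    p: list[float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.p):
            raise ValueError("ids and p differ in length")
        if any(not 0.0 <= v <= 1.0 for v in self.p):
            raise ValueError("p-values must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CorrectionResult:
    method: str  # {BH, SGoF}
    n_significant: int
    significant_ids: set[str]
    adjusted_p: Optional[list[float]] = None  # BH only, input order
    F_observed: Optional[int] = None  # SGoF only


def lrt_pvalue(lnL0: float, lnL1: float) -> float:
    """Upper-tail chi-square (df=1) p for the LRT statistic 2(lnL1 - lnL0).

    Negative differences (numerical noise from the nested null) clip to a
    statistic of 0, i.e. p = 1.
    """
    if not (np.isfinite(lnL0) and np.isfinite(lnL1)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return float(chi2.sf(stat, df=1))


def bh_fdr(pset: PValueSet) -> CorrectionResult:
    """Benjamini-Hochberg step-up adjusted p-values; significant at alpha."""
    if not pset.p:
        raise ValueError("empty p-value set")
    reject, adjusted, _, _ = multipletests(pset.p, alpha=pset.alpha, method="fdr_bh")
    significant = {i for i, r in zip(pset.ids, reject) if r}
    return CorrectionResult(
        method="BH",
        n_significant=int(reject.sum()),
        significant_ids=significant,
        adjusted_p=[float(v) for v in adjusted],
    )


def sgof(pset: PValueSet) -> CorrectionResult:
    """Sequential goodness-of-fit correction with an exact binomial metatest.

    Let F be the number of raw p-values <= alpha.  While the one-sided exact
    binomial probability of observing >= F successes in n trials at rate
    alpha is itself <= alpha, one more discovery is declared and F decreases
    by one.  The declared discoveries are the smallest raw p-values (ties
    broken by id order).
    """
    if not pset.p:
        raise ValueError("empty p-value set")
    n = len(pset.p)
    alpha = pset.alpha
    F_observed = sum(1 for v in pset.p if v <= alpha)
    F = F_observed
    n_significant = 0
    while F > 0 and float(binom.sf(F - 1, n, alpha)) <= alpha:
        n_significant += 1
        F -= 1
    order = sorted(range(n), key=lambda i: (pset.p[i], pset.ids[i]))
    significant = {pset.ids[i] for i in order[:n_significant]}
    return CorrectionResult(
        method="SGoF",
        n_significant=n_significant,
        significant_ids=significant,
        F_observed=F_observed,
    )


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study genes annotated to the term
    K: int  # study size
    m: int  # population genes annotated to the term
    M: int  # population size
    p: float
    adjusted_p: float = float("nan")
    raw_significant: bool = False
    adjusted_significant: bool = False


def hypergeometric_enrichment(
    study_ids: Sequence[str],
    population_ids: Sequence[str],
    go_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of GO terms in a study set.

    For each term with at least one study hit: p = P(X >= k) for X ~
    Hypergeom(M, m, K) with k study hits, K study genes, m population hits,
    M population genes.  Unannotated genes count toward K and M.  P-values
    are BH-adjusted across the reported terms; both the raw and adjusted
    significance flags are reported.  The annotation map is treated as flat
    (no propagation up the GO graph).
    """
    study = set(study_ids)
    population = set(population_ids)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    M = len(population)
    K = len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in go_map.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    results = []
    for term in sorted(term_study):
        k = term_study[term]
        m = term_pop[term]
        p = float(hypergeom.sf(k - 1, M, m, K))
        results.append(EnrichmentResult(term=term, k=k, K=K, m=m, M=M, p=min(p, 1.0)))
    if results:
        _, adjusted, _, _ = multipletests([r.p for r in results], alpha=alpha, method="fdr_bh")
        for r, adj in zip(results, adjusted):
            r.adjusted_p = float(adj)
            r.raw_significant = r.p <= alpha
            r.adjusted_significant = adj <= alpha
    return results
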