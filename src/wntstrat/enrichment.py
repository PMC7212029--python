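"""Weighted Kolmogorov-Smirnov gene-set enrichment with phenotype
permutation.

Genes are ranked by the Welch t statistic of LI versus LD expression
(descending, ties broken by symbol).  The enrichment score is the maximal
deviation of the weighted running sum: a set hit at rank i adds
|metric_i|^exponent / N_R (N_R = sum of |metric|^exponent over hits) and a
miss subtracts 1/(N - n_hits).  Significance comes from phenotype
permutation: class labels are reshuffled, the ranking recomputed, and the
normalised enrichment score (NES) is the observed ES divided by the mean
|ES| of same-sign permutations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .cohort import ExpressionMatrix, GeneSetCollection
from .errors import DataError
from .expression import welch_t_matrix

# Fewer same-sign permutations than this and the NES denominator is too
# unstable to report.
MIN_SAME_SIGN_PERMS = 10


@dataclass
class RankedList:
    genes: list[str]
    metrics: np.ndarray  # descending


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: Optional[float]  # None when too few same-sign permutations
    p_nominal: float
    leading_edge: list[str]
    peak_index: int
    n_perm: int
    seed: int


def _ranked_from_arrays(
    genes: np.ndarray, metric: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # Sort by metric descending, ties by gene symbol ascending.
    order = np.lexsort((genes, -metric))
    return genes[order], metric[order]


def rank_genes(
    norm: ExpressionMatrix, labels: Mapping[str, str]
) -> RankedList:
    """Rank all genes by Welch t (LI vs LD), descending."""
    from .expression import _split_groups

    li, ld = _split_groups(norm, labels)
    t, _, _, _ = welch_t_matrix(li, ld)
    genes = np.asarray(norm.values.index, dtype=object)
    g, m = _ranked_from_arrays(genes, t)
    return RankedList(genes=list(g), metrics=m)


def enrichment_score(
    ranked: RankedList, gene_set, exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted-KS running sum.  Returns (es, running_sum, peak_index);
    es is the running-sum value of maximal absolute deviation from zero,
    peak_index its first occurrence."""
    genes = np.asarray(ranked.genes, dtype=object)
    metrics = np.asarray(ranked.metrics, dtype=float)
    hit = np.isin(genes, list(gene_set))
    n = genes.size
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise DataError("gene set has empty intersection with ranked list")
    weights = np.abs(metrics) ** exponent
    nr = weights[hit].sum()
    if nr == 0:
        raise DataError("all hit metrics are zero; enrichment undefined")
    if n_hits == n:  # no misses: the sum climbs monotonically to exactly 1
        running = np.cumsum(weights)
        running = running / running[-1]
        return 1.0, running, n - 1
    step = np.where(hit, weights / nr, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[peak], -1.0, 1.0))
    return es, running, peak


def _es_only(
    metrics_sorted: np.ndarray, hit_sorted: np.ndarray, exponent: float
) -> float:
    weights = np.abs(metrics_sorted) ** exponent
    nr = weights[hit_sorted].sum()
    if nr == 0:
        return 0.0
    n = metrics_sorted.size
    n_hits = int(hit_sorted.sum())
    if n_hits == n:
        return 1.0
    step = np.where(hit_sorted, weights / nr, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    return float(np.clip(running[int(np.argmax(np.abs(running)))], -1.0, 1.0))


def leading_edge_genes(
    ranked: RankedList, gene_set, es: float, peak_index: int
) -> list[str]:
    """Set members at or before the running-sum peak for positive ES, at
    or after it for negative ES, in rank order."""
    gs = set(gene_set)
    if es >= 0:
        span = ranked.genes[: peak_index + 1]
    else:
        span = ranked.genes[peak_index:]
    return [g for g in span if g in gs]


def gsea_test(
    norm: ExpressionMatrix,
    labels: Mapping[str, str],
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA over every set in the collection.

    p_nominal uses a +1 pseudo-count over same-sign permutations; NES is
    ES over the mean |ES| of same-sign permutations, reported as None
    (with the p-value still valid) when fewer than 10 permutations share
    the observed sign.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    from .expression import _split_groups

    li, ld = _split_groups(norm, labels)
    data = np.hstack([li, ld])
    n_li = li.shape[1]
    n_total = data.shape[1]
    genes = np.asarray(norm.values.index, dtype=object)

    observed = rank_genes(norm, labels)
    hit_masks = {
        name: np.isin(np.asarray(observed.genes, dtype=object), list(sets[name]))
        for name in sets
    }
    for name, mask in hit_masks.items():
        if not mask.any():
            raise DataError(f"gene set {name!r} shares no gene with the matrix")

    obs: dict[str, tuple[float, int]] = {}
    for name in sets:
        es, _, peak = enrichment_score(observed, sets[name], exponent)
        obs[name] = (es, peak)

    rng = np.random.default_rng(seed)
    perm_es = {name: np.empty(n_perm) for name in sets}
    idx = np.arange(n_total)
    set_masks_by_gene = {
        name: np.isin(genes, list(sets[name])) for name in sets
    }
    for b in range(n_perm):
        perm = rng.permutation(idx)
        li_p = data[:, perm[:n_li]]
        ld_p = data[:, perm[n_li:]]
        t, _, _, _ = welch_t_matrix(li_p, ld_p)
        order = np.lexsort((genes, -t))
        t_sorted = t[order]
        for name in sets:
            hit_sorted = set_masks_by_gene[name][order]
            perm_es[name][b] = _es_only(t_sorted, hit_sorted, exponent)

    results: list[EnrichmentResult] = []
    for name in sets:
        es, peak = obs[name]
        es_p = perm_es[name]
        same_sign = es_p * np.sign(es if es != 0 else 1.0) > 0
        n_same = int(same_sign.sum())
        as_extreme = int((np.abs(es_p[same_sign]) >= abs(es)).sum())
        p_nominal = (1.0 + as_extreme) / (1.0 + n_same)
        if n_same >= MIN_SAME_SIGN_PERMS:
            nes = float(es / np.abs(es_p[same_sign]).mean())
        else:
            nes = None
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es,
                nes=nes,
                p_nominal=float(min(p_nominal, 1.0)),
                leading_edge=leading_edge_genes(observed, sets[name], es, peak),
                peak_index=peak,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results
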