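"""Methylation analysis: gene-level beta summaries, differential
methylation between LD and LI tumours, CIMP-stratified comparisons, and
methylation-expression correlation.

Direction is LD-relative: a probe is called *hyper* when its mean beta is
higher in ligand-dependent tumours, matching the hypermethylation of Wnt
negative regulators expected there.  Tests run on beta values directly
(an M-value transform can be applied upstream if preferred).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionMatrix, MethylationMatrix
from .errors import DataError
from .expression import benjamini_hochberg, welch_t_matrix


@dataclass(frozen=True)
class GeneMethylationSummary:
    gene: str
    sample_id: str
    mean_beta: float


@dataclass(frozen=True)
class DmpResult:
    probe: str
    gene: str
    mean_diff: float  # LD minus LI, beta units
    t_stat: float
    p: float
    q: float
    direction: str  # hyper (higher in LD) | hypo
    degenerate: bool = False


@dataclass(frozen=True)
class CimpComparison:
    gene: str
    label: str  # LD | LI
    mean_beta_cimp_pos: float
    mean_beta_cimp_neg: float
    p: float
    testable: bool


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    r: float
    p: float
    n: int


def mean_beta_per_gene(
    meth: MethylationMatrix, genes: Iterable[str]
) -> list[GeneMethylationSummary]:
    """Unweighted mean over each gene's probes, per sample."""
    out: list[GeneMethylationSummary] = []
    for gene in genes:
        probes = meth.probes_for_gene(gene)
        if not probes:
            raise DataError(f"gene {gene!r} has no mapped probe")
        means = meth.beta.loc[probes].mean(axis=0)
        for sid, value in means.items():
            out.append(GeneMethylationSummary(gene, str(sid), float(value)))
    return out


def summaries_to_frame(
    summaries: Iterable[GeneMethylationSummary],
) -> pd.DataFrame:
    """Pivot summaries to a gene x sample mean-beta frame."""
    rows = [(s.gene, s.sample_id, s.mean_beta) for s in summaries]
    frame = pd.DataFrame(rows, columns=["gene", "sample_id", "mean_beta"])
    return frame.pivot(index="gene", columns="sample_id", values="mean_beta")


def dmp_test(
    meth: MethylationMatrix, labels: Mapping[str, str]
) -> list[DmpResult]:
    """Per-probe Welch t on beta between LD and LI samples, BH-adjusted
    over all tested probes."""
    ld = [s for s in meth.samples if labels.get(s) == "LD"]
    li = [s for s in meth.samples if labels.get(s) == "LI"]
    if len(ld) < 2 or len(li) < 2:
        raise DataError(
            f"need >=2 samples per class, got LD={len(ld)}, LI={len(li)}"
        )
    a = meth.beta[ld].to_numpy(dtype=float)
    b = meth.beta[li].to_numpy(dtype=float)
    t, _, p, degenerate = welch_t_matrix(a, b)
    q = benjamini_hochberg(p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    gene_of = meth.probe_map.to_dict()
    return [
        DmpResult(
            probe=str(probe),
            gene=gene_of.get(str(probe), ""),
            mean_diff=float(diff[i]),
            t_stat=float(t[i]),
            p=float(p[i]),
            q=float(q[i]),
            direction="hyper" if diff[i] > 0 else "hypo",
            degenerate=bool(degenerate[i]),
        )
        for i, probe in enumerate(meth.beta.index)
    ]


def cimp_stratified_comparison(
    summaries: Iterable[GeneMethylationSummary],
    labels: Mapping[str, str],
    cimp_flags: Mapping[str, bool],
) -> list[CimpComparison]:
    """For each gene and class, compare mean beta between CIMP-positive
    and CIMP-negative samples (Welch, two-sided).  Strata with fewer than
    two samples are reported as not testable rather than dropped."""
    frame = summaries_to_frame(summaries)
    out: list[CimpComparison] = []
    for gene in frame.index:
        for label in ("LD", "LI"):
            samples = [
                s for s in frame.columns
                if labels.get(s) == label and s in cimp_flags
            ]
            pos = np.array(
                [frame.loc[gene, s] for s in samples if cimp_flags[s]]
            )
            neg = np.array(
                [frame.loc[gene, s] for s in samples if not cimp_flags[s]]
            )
            testable = len(pos) >= 2 and len(neg) >= 2
            if testable:
                t, p = stats.ttest_ind(pos, neg, equal_var=False)
                p = float(p)
                if np.isnan(p):  # zero variance in both strata
                    p = 1.0
            else:
                p = float("nan")
            out.append(
                CimpComparison(
                    gene=str(gene),
                    label=label,
                    mean_beta_cimp_pos=float(pos.mean()) if len(pos) else float("nan"),
                    mean_beta_cimp_neg=float(neg.mean()) if len(neg) else float("nan"),
                    p=p,
                    testable=testable,
                )
            )
    return out


def meth_expr_correlation(
    summaries: Iterable[GeneMethylationSummary],
    norm: ExpressionMatrix,
) -> list[CorrelationResult]:
    """Pearson correlation between per-sample gene-level mean beta and
    log-CPM of the same gene, over samples present in both layers."""
    frame = summaries_to_frame(summaries)
    out: list[CorrelationResult] = []
    for gene in frame.index:
        if gene not in norm.values.index:
            raise DataError(f"gene {gene!r} absent from expression matrix")
        shared = [s for s in frame.columns if s in norm.values.columns]
        beta = frame.loc[gene, shared].to_numpy(dtype=float)
        expr = norm.values.loc[gene, shared].to_numpy(dtype=float)
        keep = ~(np.isnan(beta) | np.isnan(expr))
        beta, expr = beta[keep], expr[keep]
        if beta.size < 3:
            raise DataError(f"gene {gene!r}: fewer than 3 shared samples")
        if beta.std(ddof=1) == 0 or expr.std(ddof=1) == 0:
            raise DataError(f"gene {gene!r}: zero variance, correlation undefined")
        r, p = stats.pearsonr(beta, expr)
        out.append(
            CorrelationResult(gene=str(gene), r=float(r), p=float(p), n=int(beta.size))
        )
    return out
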