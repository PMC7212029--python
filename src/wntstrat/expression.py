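"""Expression-side statistics: log-CPM normalisation, cohort-relative
z-score outlier calling, Welch two-group differential expression with
Benjamini-Hochberg FDR control, and mean-z signature scoring.

All class comparisons are LI versus LD on log2(1 + CPM) values; the mean
difference is reported as LI minus LD so positive values mean higher
expression in ligand-independent tumours.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix
from .errors import DataError


@dataclass(frozen=True)
class OutlierCall:
    gene: str
    sample_id: str
    z: float
    is_outlier: bool


@dataclass(frozen=True)
class DeResult:
    gene: str
    mean_diff: float  # LI minus LD, log2 units
    t_stat: float
    df: float
    p: float
    q: float
    degenerate: bool = False  # zero variance in both groups


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    signature: str
    score: float


def log_cpm(matrix: ExpressionMatrix, prior_count: float = 1.0) -> ExpressionMatrix:
    """log2(prior_count + 1e6 * count / library_size) per cell.

    With the default prior of 1, a zero count maps to exactly 0 and the
    transform is invariant to rescaling a sample's counts.
    """
    if matrix.space != "counts":
        raise DataError(f"log_cpm expects counts, got space={matrix.space!r}")
    counts = matrix.values.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise DataError(
            f"zero library size for sample {matrix.values.columns[zero[0]]!r}"
        )
    cpm = 1e6 * counts / libsize[None, :]
    values = pd.DataFrame(
        np.log2(prior_count + cpm),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(values=values, space="log_cpm")


def zscore_outliers(
    norm: ExpressionMatrix, genes: Iterable[str], threshold: float = 2.0
) -> list[OutlierCall]:
    """Cohort-relative z-scores per gene (sample standard deviation, n-1);
    a call is an outlier when z >= threshold (inclusive)."""
    if norm.values.shape[1] < 3:
        raise DataError("z-score outlier calling needs at least 3 samples")
    calls: list[OutlierCall] = []
    for gene in genes:
        if gene not in norm.values.index:
            raise DataError(f"gene {gene!r} absent from matrix")
        x = norm.values.loc[gene].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DataError(f"gene {gene!r} has zero variance")
        z = (x - x.mean()) / sd
        for sid, zi in zip(norm.values.columns, z):
            calls.append(
                OutlierCall(gene=gene, sample_id=sid, z=float(zi),
                            is_outlier=bool(zi >= threshold))
            )
    return calls


def welch_t_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample t over rows: ``a`` and ``b`` are
    feature x sample arrays for the two groups.  Returns (t, df, p,
    degenerate) where degenerate marks rows with zero variance in both
    groups (reported as t=0, p=1)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, float(na + nb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, df, p, degenerate


def _split_groups(
    norm: ExpressionMatrix, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    ld = [s for s in norm.values.columns if labels.get(s) == "LD"]
    li = [s for s in norm.values.columns if labels.get(s) == "LI"]
    if len(ld) < 2 or len(li) < 2:
        raise DataError(
            f"need >=2 samples per class, got LD={len(ld)}, LI={len(li)}"
        )
    return (
        norm.values[li].to_numpy(dtype=float),
        norm.values[ld].to_numpy(dtype=float),
    )


def differential_expression(
    norm: ExpressionMatrix, labels: Mapping[str, str]
) -> list[DeResult]:
    """Per-gene Welch t of LI versus LD log-CPM with BH-adjusted q over
    all tested genes."""
    li, ld = _split_groups(norm, labels)
    t, df, p, degenerate = welch_t_matrix(li, ld)
    q = benjamini_hochberg(p)
    mean_diff = li.mean(axis=1) - ld.mean(axis=1)
    return [
        DeResult(
            gene=str(g),
            mean_diff=float(mean_diff[i]),
            t_stat=float(t[i]),
            df=float(df[i]),
            p=float(p[i]),
            q=float(q[i]),
            degenerate=bool(degenerate[i]),
        )
        for i, g in enumerate(norm.values.index)
    ]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values over exactly the supplied tests."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def signature_score(
    norm: ExpressionMatrix, genes: Iterable[str], name: str = "signature"
) -> tuple[list[SignatureScore], list[str]]:
    """Per-sample mean of gene-wise z-scores of log-CPM over the signature
    genes.  Returns (scores, dropped_genes); genes absent from the matrix
    are dropped and reported."""
    genes = list(genes)
    present = [g for g in genes if g in norm.values.index]
    dropped = [g for g in genes if g not in norm.values.index]
    if not present:
        raise DataError(f"no signature gene of {name!r} present in matrix")
    sub = norm.values.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = present[int(np.flatnonzero(sd == 0)[0])]
        raise DataError(f"signature gene {bad!r} has zero variance")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = z.mean(axis=0)
    return (
        [
            SignatureScore(sample_id=str(s), signature=name, score=float(v))
            for s, v in zip(norm.values.columns, scores)
        ],
        dropped,
    )
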