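"""Single-gene expression biomarker for ligand-dependent tumours.

The positive class is LD (the group eligible for Wnt ligand inhibition)
and the decision score is *low* expression: a sample is called LD when
its expression falls below the threshold.  The AUC therefore equals
P(x_LI > x_LD) with ties at weight 0.5 — the orientation in which higher
expression indicates ligand independence.  The operating threshold is
chosen to maximise sensitivity + specificity over the midpoint cutpoints
of the observed scores, and its confidence interval comes from a
stratified percentile bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.stats import rankdata

from .cohort import ExpressionMatrix
from .errors import DataError


@dataclass
class RocCurve:
    """ROC curve for the rule 'call LD when expression < threshold'.

    Points are ordered by decreasing threshold, from (sens=1, spec=0) at
    +inf to (sens=0, spec=1) at -inf.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray  # fraction of LD called LD
    specificity: np.ndarray  # fraction of LI called LI


@dataclass(frozen=True)
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_ld: int
    n_li: int
    n_boot: int
    seed: int


@dataclass(frozen=True)
class ThresholdRule:
    gene: str
    threshold: float
    achieved_sensitivity: float
    achieved_specificity: float


@dataclass
class PerformanceReport:
    tp: int  # LD called LD
    fn: int
    tn: int  # LI called LI
    fp: int
    sensitivity: float
    specificity: float
    ex_scores: dict[str, float] = field(default_factory=dict)


def _split_scores(
    scores: Mapping[str, float], labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    bad = [s for s, l in labels.items() if l not in ("LD", "LI")]
    if bad:
        raise DataError(
            f"labels must be LD/LI only (EX must be removed first); "
            f"offending sample {bad[0]!r}"
        )
    ld = np.array([scores[s] for s, l in labels.items() if l == "LD"], dtype=float)
    li = np.array([scores[s] for s, l in labels.items() if l == "LI"], dtype=float)
    if ld.size == 0 or li.size == 0:
        raise DataError(
            f"both classes must be nonempty, got LD={ld.size}, LI={li.size}"
        )
    return ld, li


def concordance_auc(ld: np.ndarray, li: np.ndarray) -> float:
    """P(x_LI > x_LD) + 0.5 * P(x_LI = x_LD), via midranks."""
    pooled = np.concatenate([li, ld])
    ranks = rankdata(pooled)
    r_li = ranks[: li.size].sum()
    u = r_li - li.size * (li.size + 1) / 2.0
    return float(u / (li.size * ld.size))


def roc_curve(
    scores: Mapping[str, float], labels: Mapping[str, str]
) -> tuple[RocCurve, float]:
    """ROC over midpoint cutpoints (plus +/-inf sentinels) and the
    concordance AUC."""
    ld, li = _split_scores(scores, labels)
    distinct = np.unique(np.concatenate([ld, li]))
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], midpoints[::-1], [-np.inf]))
    sens = np.array([(ld < t).mean() for t in thresholds])
    spec = np.array([(li >= t).mean() for t in thresholds])
    curve = RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)
    return curve, concordance_auc(ld, li)


def trapezoid_auc(curve: RocCurve) -> float:
    """Area under sensitivity vs (1 - specificity); equals the
    concordance AUC."""
    fpr = 1.0 - curve.specificity
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def bootstrap_ci(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> RocSummary:
    """Stratified percentile bootstrap interval for the AUC."""
    ld, li = _split_scores(scores, labels)
    if ld.size < 2 or li.size < 2:
        raise DataError("bootstrap needs >=2 samples per class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ld_b = ld[rng.integers(0, ld.size, ld.size)]
        li_b = li[rng.integers(0, li.size, li.size)]
        aucs[b] = concordance_auc(ld_b, li_b)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    auc = concordance_auc(ld, li)
    return RocSummary(
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        ci_method=f"stratified percentile bootstrap (B={n_boot})",
        n_ld=int(ld.size),
        n_li=int(li.size),
        n_boot=n_boot,
        seed=seed,
    )


def select_threshold(curve: RocCurve, gene: str = "AXIN2") -> ThresholdRule:
    """Cutpoint maximising sensitivity + specificity; ties broken by
    higher specificity, then lower threshold."""
    total = curve.sensitivity + curve.specificity
    best = 0
    for i in range(1, total.size):
        if total[i] > total[best] + 1e-12:
            best = i
        elif abs(total[i] - total[best]) <= 1e-12:
            if curve.specificity[i] > curve.specificity[best] + 1e-12:
                best = i
            elif (
                abs(curve.specificity[i] - curve.specificity[best]) <= 1e-12
                and curve.thresholds[i] < curve.thresholds[best]
            ):
                best = i
    return ThresholdRule(
        gene=gene,
        threshold=float(curve.thresholds[best]),
        achieved_sensitivity=float(curve.sensitivity[best]),
        achieved_specificity=float(curve.specificity[best]),
    )


def apply_classifier(
    rule: ThresholdRule,
    norm: ExpressionMatrix,
    labels_truth: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, str], Optional[PerformanceReport]]:
    """Call LD when expression < threshold, LI otherwise (the boundary
    goes to LI).  If truth labels are supplied, EX samples are reported
    with their scores but never enter the confusion matrix."""
    if rule.gene not in norm.values.index:
        raise DataError(f"gene {rule.gene!r} absent from matrix")
    expr = norm.values.loc[rule.gene]
    predictions = {
        str(s): ("LD" if float(v) < rule.threshold else "LI")
        for s, v in expr.items()
    }
    if labels_truth is None:
        return predictions, None
    tp = fn = tn = fp = 0
    ex_scores: dict[str, float] = {}
    for sid, truth in labels_truth.items():
        if sid not in predictions:
            continue
        if truth == "LD":
            if predictions[sid] == "LD":
                tp += 1
            else:
                fn += 1
        elif truth == "LI":
            if predictions[sid] == "LI":
                tn += 1
            else:
                fp += 1
        else:  # EX: report, never score
            ex_scores[sid] = float(expr[sid])
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    report = PerformanceReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, ex_scores=ex_scores,
    )
    return predictions, report
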