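#!/usr/bin/env python
"""Methylation of Wnt negative regulators in LD versus LI tumours.

Tests per-probe differential methylation (expected LD-hypermethylated
for the coupled genes), contrasts CIMP-positive and CIMP-negative strata
(AXIN2/NKD1 methylation is CIMP-independent; NOTUM/APCDD1 is CIMP-driven),
and quantifies the methylation-expression anticorrelation.
"""
import sys
from pathlib import Path

import pandas as pd

from wntstrat import (
    cimp_stratified_comparison,
    dmp_test,
    log_cpm,
    mean_beta_per_gene,
    meth_expr_correlation,
)
from wntstrat.io import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not (cohort_dir / "labels.tsv").exists():
        print("run analysis/02_classify_drivers.py first", file=sys.stderr)
        return 1
    bundle = read_cohort(cohort_dir)
    labels_frame = pd.read_csv(cohort_dir / "labels.tsv", sep="\t")
    labels = {
        r.sample_id: r.label for r in labels_frame.itertuples()
        if r.label in ("LD", "LI")
    }
    cimp = {a.sample_id: a.cimp_status == "positive" for a in bundle.annotation}
    genes = sorted(set(bundle.methylation.probe_map.values))
    norm = log_cpm(bundle.expression)

    dmps = dmp_test(bundle.methylation, labels)
    dmp_frame = pd.DataFrame(
        [{"probe": d.probe, "gene": d.gene, "mean_diff_ld_minus_li": d.mean_diff,
          "q": d.q, "direction": d.direction} for d in dmps]
    ).sort_values("q")

    summaries = mean_beta_per_gene(bundle.methylation, genes)
    cimp_rows = cimp_stratified_comparison(summaries, labels, cimp)
    cimp_frame = pd.DataFrame(
        [{"gene": r.gene, "class": r.label,
          "beta_cimp_pos": r.mean_beta_cimp_pos,
          "beta_cimp_neg": r.mean_beta_cimp_neg,
          "p": r.p, "testable": r.testable} for r in cimp_rows]
    )
    corr = meth_expr_correlation(
        [s for s in summaries if s.gene in ("AXIN2", "NKD1")], norm
    )
    corr_frame = pd.DataFrame(
        [{"gene": c.gene, "r": c.r, "p": c.p, "n": c.n} for c in corr]
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    dmp_frame.to_csv(results / "05_dmp.tsv", sep="\t", index=False)
    cimp_frame.to_csv(results / "05_cimp_comparison.tsv", sep="\t", index=False)
    corr_frame.to_csv(results / "05_meth_expr_correlation.tsv", sep="\t",
                      index=False)

    n_sig = (dmp_frame["q"] < 0.05).sum()
    n_hyper = ((dmp_frame["q"] < 0.05) & (dmp_frame["direction"] == "hyper")).sum()
    print(f"{n_sig} differentially methylated probes at q<0.05 "
          f"({n_hyper} hypermethylated in LD)")
    print(corr_frame.to_string(index=False))
    print("\nCIMP-stratified comparison (linear-coupled genes should be "
          "CIMP-independent):")
    print(cimp_frame.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
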