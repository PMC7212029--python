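#!/usr/bin/env python
"""Gene-set enrichment of Wnt target subsets between LI and LD tumours.

Runs phenotype-permutation weighted-KS enrichment over the packaged Wnt
target gene sets.  The negative-regulator set is expected strongly
enriched in LI tumours; the placeholder sets (background genes) are not.
"""
import sys
from pathlib import Path

import pandas as pd

from wntstrat import gsea_test, log_cpm
from wntstrat.io import read_cohort
from wntstrat.pipeline import packaged_gene_sets

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
    norm = log_cpm(bundle.expression)
    results_list = gsea_test(
        norm, labels, packaged_gene_sets(), n_perm=1000, seed=7
    )
    frame = pd.DataFrame(
        [
            {"set": r.set_name, "es": r.es, "nes": r.nes,
             "p_nominal": r.p_nominal,
             "leading_edge": ";".join(r.leading_edge)}
            for r in results_list
        ]
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    frame.to_csv(results / "04_gsea.tsv", sep="\t", index=False)
    print(frame[["set", "es", "nes", "p_nominal"]].to_string(index=False))
    nr = next(r for r in results_list if r.set_name == "wnt_negative_regulators")
    print(f"\nnegative-regulator leading edge: {', '.join(nr.leading_edge)}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
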