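#!/usr/bin/env python
"""Contrast Wnt negative-regulator expression between LI and LD tumours.

Normalises counts to log-CPM, runs Welch differential expression over the
whole panel (BH-corrected), and reports the five negative regulators —
all expected higher in ligand-independent tumours, where intact feedback
loops are functionally redundant rather than epigenetically silenced.
Also scores the fibroblast signature in RSPO-high versus RSPO-fusion
tumours (stromal RSPO source).
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from wntstrat import differential_expression, log_cpm, signature_score
from wntstrat.cohort import NEGATIVE_REGULATORS
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
        r.sample_id: r.label
        for r in labels_frame.itertuples()
        if r.label in ("LD", "LI")
    }
    norm = log_cpm(bundle.expression)
    de = differential_expression(norm, labels)
    frame = pd.DataFrame(
        [
            {"gene": r.gene, "mean_diff_li_minus_ld": r.mean_diff,
             "t": r.t_stat, "p": r.p, "q": r.q}
            for r in de
        ]
    ).sort_values("q")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    nr = frame[frame["gene"].isin(NEGATIVE_REGULATORS)]
    nr.to_csv(results / "03_de_negative_regulators.tsv", sep="\t", index=False)

    caf = packaged_gene_sets("caf_signature.gmt")
    scores, _ = signature_score(norm, caf["caf_signature"], "caf")
    score_map = {s.sample_id: s.score for s in scores}
    subtype = dict(zip(labels_frame["sample_id"], labels_frame["ld_subtype"]))
    by = {
        st: np.mean([v for s, v in score_map.items() if subtype.get(s) == st])
        for st in ("RSPO_FUSION", "RSPO_HIGH")
    }

    print(nr.to_string(index=False))
    consensus = nr[(nr["q"] < 0.05) & (nr["mean_diff_li_minus_ld"] > 0)]
    print(f"\n{len(consensus)}/5 negative regulators significantly higher in LI")
    print(f"CAF signature mean score: RSPO-high {by['RSPO_HIGH']:.2f} vs "
          f"RSPO-fusion {by['RSPO_FUSION']:.2f} (stromal source in RSPO-high)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
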