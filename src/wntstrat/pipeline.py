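"""End-to-end orchestration: simulate -> classify -> expression -> GSEA ->
methylation -> biomarker, with a deterministic machine-readable report.

Each stage is a thin wrapper over the corresponding module so the CLI,
the numbered analysis scripts, and the acceptance script all run exactly
the same code.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .biomarker import apply_classifier, bootstrap_ci, roc_curve, select_threshold
from .cohort import (
    NEGATIVE_REGULATORS,
    CohortBundle,
    GeneSetCollection,
    validate_bundle,
)
from .config import SimulationConfig
from .drivers import classify_cohort, exclusivity_summary
from .enrichment import gsea_test
from .errors import DataError
from .expression import differential_expression, log_cpm, signature_score
from .io import read_gmt, write_cohort
from .methylation import (
    cimp_stratified_comparison,
    dmp_test,
    mean_beta_per_gene,
    meth_expr_correlation,
)
from .simulate import SyntheticTruth, default_junction_library, simulate_cohort


def packaged_gene_sets(name: str = "wnt_sets.gmt") -> GeneSetCollection:
    """Load one of the GMT files shipped with the package (the Wnt target
    subsets are synthetic placeholders except the negative-regulator set)."""
    with resources.as_file(
        resources.files("wntstrat.data").joinpath(name)
    ) as path:
        return read_gmt(path)


def labels_to_mapping(labels) -> dict[str, str]:
    return {l.sample_id: l.label for l in labels}


def ld_li_only(label_map: Mapping[str, str]) -> dict[str, str]:
    return {s: l for s, l in label_map.items() if l in ("LD", "LI")}


def run_full(
    config: SimulationConfig,
    out_dir: Optional[Path] = None,
    n_perm: int = 1000,
    n_boot: int = 2000,
    biomarker_gene: str = "AXIN2",
) -> dict:
    """Run the whole pipeline on one synthetic cohort and return the
    report dictionary (also written to ``out_dir/report.json`` when an
    output directory is given).  Deterministic in ``config.seed``."""
    bundle, truth = simulate_cohort(config)
    library = default_junction_library(config.seed)
    violations = validate_bundle(bundle)
    if violations:
        raise DataError(f"simulated bundle failed validation: {violations[:3]}")

    labels, profiles, fusion_calls = classify_cohort(
        bundle, library, min_overlap=config.min_overlap
    )
    label_map = labels_to_mapping(labels)
    core = ld_li_only(label_map)
    excl = exclusivity_summary(profiles)

    norm = log_cpm(bundle.expression)
    de = differential_expression(norm, core)
    de_by_gene = {r.gene: r for r in de}

    sets = packaged_gene_sets("wnt_sets.gmt")
    gsea = gsea_test(norm, core, sets, n_perm=n_perm, seed=config.seed)

    caf = packaged_gene_sets("caf_signature.gmt")
    caf_scores, _ = signature_score(norm, caf["caf_signature"], "caf_signature")
    caf_map = {s.sample_id: s.score for s in caf_scores}
    subtype_map = {l.sample_id: l.ld_subtype for l in labels}
    caf_by_subtype = {}
    for subtype in ("RSPO_FUSION", "RSPO_HIGH"):
        vals = [caf_map[s] for s, st in subtype_map.items() if st == subtype]
        caf_by_subtype[subtype] = (
            sum(vals) / len(vals) if vals else float("nan")
        )

    meth_report = {}
    if bundle.methylation is not None:
        meth_genes = sorted(set(bundle.methylation.probe_map.values))
        summaries = mean_beta_per_gene(bundle.methylation, meth_genes)
        dmps = dmp_test(bundle.methylation, core)
        cimp_map = {
            a.sample_id: a.cimp_status == "positive" for a in bundle.annotation
        }
        cimp_rows = cimp_stratified_comparison(summaries, core, cimp_map)
        corr = meth_expr_correlation(summaries, norm)
        meth_report = {
            "n_probes_tested": len(dmps),
            "n_dmp_q05": sum(1 for d in dmps if d.q < 0.05),
            "n_dmp_q05_hyper": sum(
                1 for d in dmps if d.q < 0.05 and d.direction == "hyper"
            ),
            "correlation": {
                c.gene: {"r": round(c.r, 6), "p": float(f"{c.p:.6g}"), "n": c.n}
                for c in corr
            },
            "cimp_comparison": [
                {
                    "gene": row.gene,
                    "label": row.label,
                    "mean_beta_cimp_pos": round(row.mean_beta_cimp_pos, 6),
                    "mean_beta_cimp_neg": round(row.mean_beta_cimp_neg, 6),
                    "p": None if not row.testable else float(f"{row.p:.6g}"),
                    "testable": row.testable,
                }
                for row in cimp_rows
            ],
        }

    scores = {
        s: float(norm.values.loc[biomarker_gene, s]) for s in core
    }
    curve, auc = roc_curve(scores, core)
    summary = bootstrap_ci(scores, core, n_boot=n_boot, seed=config.seed)
    rule = select_threshold(curve, gene=biomarker_gene)
    _, perf = apply_classifier(rule, norm, label_map)

    label_counts = {
        "LD": sum(1 for l in labels if l.label == "LD"),
        "LI": sum(1 for l in labels if l.label == "LI"),
        "EX": sum(1 for l in labels if l.label == "EX"),
    }
    truth_classes = truth.classes()
    recovered = sum(
        1 for l in labels if truth_classes.get(l.sample_id) == l.label
    )

    report = {
        "config": {"n_samples": config.n_samples, "seed": config.seed},
        "classification": {
            "labels": label_counts,
            "n_fusion_calls": len(fusion_calls),
            "driver_burden": excl["burden"],
            "truth_class_agreement": round(recovered / max(config.n_samples, 1), 6),
        },
        "differential_expression": {
            gene: {
                "mean_diff_li_minus_ld": round(de_by_gene[gene].mean_diff, 6),
                "q": float(f"{de_by_gene[gene].q:.6g}"),
            }
            for gene in NEGATIVE_REGULATORS
            if gene in de_by_gene
        },
        "gsea": {
            r.set_name: {
                "es": round(r.es, 6),
                "nes": None if r.nes is None else round(r.nes, 6),
                "p_nominal": float(f"{r.p_nominal:.6g}"),
                "leading_edge": r.leading_edge,
            }
            for r in gsea
        },
        "caf_signature_mean_by_subtype": {
            k: (None if v != v else round(v, 6)) for k, v in caf_by_subtype.items()
        },
        "methylation": meth_report,
        "biomarker": {
            "gene": biomarker_gene,
            "auc": round(summary.auc, 6),
            "ci_low": round(summary.ci_low, 6),
            "ci_high": round(summary.ci_high, 6),
            "threshold_log_cpm": round(rule.threshold, 6),
            "sensitivity": round(perf.sensitivity, 6),
            "specificity": round(perf.specificity, 6),
            "n_ld": summary.n_ld,
            "n_li": summary.n_li,
            "n_ex_reported": len(perf.ex_scores),
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(bundle, out_dir / "cohort", truth=truth, library=library)
        config.to_yaml(out_dir / "cohort" / "config.lock.yaml")
        with (out_dir / "report.json").open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
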