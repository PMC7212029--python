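"""Domain containers for one multi-omic tumour cohort.

A cohort couples a sample annotation table (CIMP status, CMS label) with a
mutation table, a gene x sample expression matrix, optionally a probe x
sample methylation beta matrix with a probe-to-gene map, and optionally
per-sample RNA-seq reads used for RSPO fusion detection.  All downstream
stages consume these containers rather than raw files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CIMP_VALUES = ("positive", "negative", "unknown")
CMS_VALUES = ("CMS1", "CMS2", "CMS3", "CMS4", "unknown")
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_site",
    "inframe",
    "silent",
    "other",
)
EXPRESSION_SPACES = ("counts", "log_cpm", "log_arbitrary")

#: Wnt negative-regulator feedback genes profiled throughout the analysis.
NEGATIVE_REGULATORS = ("AXIN2", "NKD1", "APCDD1", "NOTUM", "DKK4")
RSPO_GENES = ("RSPO2", "RSPO3")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: cohort membership, CIMP status and CMS label."""

    sample_id: str
    cohort: str
    cimp_status: str = "unknown"
    cms: str = "unknown"

    def __post_init__(self) -> None:
        if self.cimp_status not in CIMP_VALUES:
            raise ValueError(
                f"cimp_status {self.cimp_status!r} not in {CIMP_VALUES}"
            )
        if self.cms not in CMS_VALUES:
            raise ValueError(f"cms {self.cms!r} not in {CMS_VALUES}")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call in MAF-like terms.

    ``variant_class`` uses a closed vocabulary; fusions never appear here
    (they are detected from reads).  ``protein_position`` is 1-based and
    optional.
    """

    sample_id: str
    gene: str
    variant_class: str
    protein_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"variant_class {self.variant_class!r} not in {VARIANT_CLASSES}"
            )
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein_position must be >= 1 when present")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values in a declared space.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns.
    ``space`` is one of counts / log_cpm / log_arbitrary; when counts, all
    values are nonnegative integers.
    """

    values: pd.DataFrame
    space: str

    def __post_init__(self) -> None:
        if self.space not in EXPRESSION_SPACES:
            raise ValueError(f"space {self.space!r} not in {EXPRESSION_SPACES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationMatrix:
    """Probe x sample beta values in [0,1] plus a probe-to-gene map."""

    beta: pd.DataFrame
    probe_map: pd.Series  # index: probe id, value: gene symbol

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def probes_for_gene(self, gene: str) -> list[str]:
        return list(self.probe_map.index[self.probe_map.values == gene])


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, genes) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        genes = frozenset(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, genes)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class FastqRead:
    """One sequencing read (plain record; qualities are constant in the
    synthetic generator and never interpreted)."""

    read_id: str
    sequence: str
    quality: str


@dataclass
class CohortBundle:
    """All layers of one cohort, aligned on sample id."""

    annotation: list[SampleAnnotation]
    mutations: list[MutationRecord]
    expression: ExpressionMatrix
    methylation: Optional[MethylationMatrix] = None
    reads: Optional[dict[str, list[FastqRead]]] = None

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotation]


def validate_bundle(bundle: CohortBundle) -> list[str]:
    """Check every cross-layer invariant; return a list of human-readable
    violations (empty list = valid).  Violations are data, not exceptions."""
    violations: list[str] = []
    ann_ids = [a.sample_id for a in bundle.annotation]
    seen = set()
    for sid in ann_ids:
        if sid in seen:
            violations.append(f"duplicate sample_id in annotation: {sid}")
        seen.add(sid)
    known = set(ann_ids)

    for rec in bundle.mutations:
        if rec.sample_id not in known:
            violations.append(
                f"mutation table references unknown sample {rec.sample_id}"
            )

    for sid in bundle.expression.samples:
        if sid not in known:
            violations.append(f"expression matrix references unknown sample {sid}")
    if bundle.expression.space == "counts":
        vals = bundle.expression.values.to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            violations.append("counts matrix contains negative or non-integer values")

    if bundle.methylation is not None:
        meth = bundle.methylation
        for sid in meth.samples:
            if sid not in known:
                violations.append(
                    f"methylation matrix references unknown sample {sid}"
                )
        beta = meth.beta
        bad = (beta.lt(0) | beta.gt(1))
        if bad.to_numpy().any():
            for probe in beta.index[bad.any(axis=1)]:
                for sid in beta.columns[bad.loc[probe]]:
                    violations.append(
                        f"beta value out of [0,1] at probe {probe}, sample {sid}"
                    )
        probe_ids = set(meth.probes)
        for probe in meth.probe_map.index:
            if probe not in probe_ids:
                violations.append(
                    f"probe_map references unknown probe {probe}"
                )
        expr_samples = set(bundle.expression.samples)
        if not expr_samples.intersection(meth.samples):
            violations.append("expression and methylation share no sample")

    if bundle.reads is not None:
        for sid in bundle.reads:
            if sid not in known:
                violations.append(f"reads reference unknown sample {sid}")

    return violations
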