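"""Per-sample Wnt driver interpretation and LD / LI / EX class assignment.

Evidence is collected into a :class:`WntDriverProfile` per sample:
truncating APC or hotspot CTNNB1 mutations are ligand-independent (LI)
drivers; RNF43 truncations, RSPO2/3 fusions and fusion-negative RSPO
expression outliers (``rspo_high``) are ligand-dependent (LD) drivers.
Samples with drivers of both classes, or with none, are excluded (EX)
from downstream class comparisons but tracked with a machine-readable
reason.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohort import CohortBundle, MutationRecord
from .expression import OutlierCall, log_cpm, zscore_outliers
from .fusions import FusionCall, JunctionLibrary, detect_fusions
from .simulate import DEFAULT_CTNNB1_HOTSPOTS

DRIVER_FLAGS = ("apc_lof", "ctnnb1_act", "rnf43_lof", "rspo_fusion", "rspo_high")
LI_FLAGS = ("apc_lof", "ctnnb1_act")
LD_FLAGS = ("rnf43_lof", "rspo_fusion", "rspo_high")

#: Variant classes treated as loss of function for APC / RNF43.
LOF_CLASSES = frozenset({"nonsense", "frameshift", "splice_site"})


@dataclass
class WntDriverProfile:
    sample_id: str
    flags: dict[str, bool] = field(
        default_factory=lambda: {f: False for f in DRIVER_FLAGS}
    )
    evidence: list[tuple[str, object]] = field(default_factory=list)

    def set_flag(self, flag: str, source: object) -> None:
        self.flags[flag] = True
        self.evidence.append((flag, source))

    @property
    def n_flags(self) -> int:
        return sum(self.flags.values())


@dataclass(frozen=True)
class ClassLabel:
    sample_id: str
    label: str  # LD | LI | EX
    ld_subtype: str  # RSPO_FUSION | RSPO_HIGH | RNF43 | AMBIGUOUS | none
    reason: str


def classify_mutation(
    record: MutationRecord,
    hotspots: Optional[Mapping[str, frozenset[int]]] = None,
) -> Optional[str]:
    """Map one mutation to a driver flag, or None if non-functional.

    APC/RNF43 truncations (nonsense, frameshift, splice site) are loss of
    function; CTNNB1 missense mutations at configured hotspot codons are
    activating.  Everything else — silent, missense outside hotspots,
    other genes — carries no driver weight.
    """
    if hotspots is None:
        hotspots = {"CTNNB1": DEFAULT_CTNNB1_HOTSPOTS}
    if record.gene == "APC" and record.variant_class in LOF_CLASSES:
        return "apc_lof"
    if record.gene == "RNF43" and record.variant_class in LOF_CLASSES:
        return "rnf43_lof"
    if (
        record.gene == "CTNNB1"
        and record.variant_class == "missense"
        and record.protein_position is not None
        and record.protein_position in hotspots.get("CTNNB1", frozenset())
    ):
        return "ctnnb1_act"
    return None


def call_rspo_high(
    outliers: Iterable[OutlierCall], fusions: Iterable[FusionCall]
) -> set[str]:
    """Samples with outlier RSPO2/3 expression (z above threshold) but no
    fusion call for any RSPO gene: stromal RSPO-high candidates."""
    fusion_samples = {c.sample_id for c in fusions}
    return {
        o.sample_id
        for o in outliers
        if o.is_outlier and o.sample_id not in fusion_samples
    }


def assign_class(profile: WntDriverProfile) -> ClassLabel:
    """LD / LI / EX assignment from a driver profile.

    Concurrent LD and LI evidence, or no evidence at all, yields EX with
    the corresponding reason.  A pure-LD profile with more than one LD
    flag is labelled subtype AMBIGUOUS (kept as LD but excluded from
    subtype-level analyses).
    """
    li_evidence = any(profile.flags[f] for f in LI_FLAGS)
    ld_evidence = any(profile.flags[f] for f in LD_FLAGS)
    sid = profile.sample_id
    if li_evidence and ld_evidence:
        return ClassLabel(sid, "EX", "none", "concurrent")
    if not li_evidence and not ld_evidence:
        return ClassLabel(sid, "EX", "none", "no driver")
    if li_evidence:
        return ClassLabel(sid, "LI", "none", "LI driver")
    n_ld = sum(profile.flags[f] for f in LD_FLAGS)
    if n_ld > 1:
        return ClassLabel(sid, "LD", "AMBIGUOUS", "multiple LD drivers")
    if profile.flags["rspo_fusion"]:
        subtype = "RSPO_FUSION"
    elif profile.flags["rnf43_lof"]:
        subtype = "RNF43"
    else:
        subtype = "RSPO_HIGH"
    return ClassLabel(sid, "LD", subtype, "LD driver")


def exclusivity_summary(profiles: Iterable[WntDriverProfile]) -> dict:
    """Counts of samples carrying 0 / 1 / >=2 driver flags and the 5x5
    pairwise co-occurrence matrix (diagonal = per-flag totals)."""
    profiles = list(profiles)
    burden = Counter()
    matrix = pd.DataFrame(0, index=DRIVER_FLAGS, columns=DRIVER_FLAGS, dtype=int)
    for p in profiles:
        active = [f for f in DRIVER_FLAGS if p.flags[f]]
        k = len(active)
        burden["0" if k == 0 else "1" if k == 1 else ">=2"] += 1
        for a in active:
            matrix.loc[a, a] += 1
            for b in active:
                if a != b:
                    matrix.loc[a, b] += 1
    return {
        "n_samples": len(profiles),
        "burden": {key: burden.get(key, 0) for key in ("0", "1", ">=2")},
        "co_occurrence": matrix,
    }


def build_profiles(
    sample_ids: Iterable[str],
    mutations: Iterable[MutationRecord],
    fusion_calls: Iterable[FusionCall],
    rspo_high_samples: Iterable[str],
    hotspots: Optional[Mapping[str, frozenset[int]]] = None,
) -> list[WntDriverProfile]:
    """Fold mutation flags, fusion calls and RSPO-high calls into one
    driver profile per sample."""
    profiles = {sid: WntDriverProfile(sample_id=sid) for sid in sample_ids}
    for rec in mutations:
        flag = classify_mutation(rec, hotspots)
        if flag is not None and rec.sample_id in profiles:
            if not profiles[rec.sample_id].flags[flag]:
                profiles[rec.sample_id].set_flag(flag, rec)
            else:
                profiles[rec.sample_id].evidence.append((flag, rec))
    for call in fusion_calls:
        if call.sample_id in profiles:
            profiles[call.sample_id].set_flag("rspo_fusion", call)
    for sid in rspo_high_samples:
        if sid in profiles:
            profiles[sid].set_flag("rspo_high", sid)
    return list(profiles.values())


def classify_cohort(
    bundle: CohortBundle,
    library: Optional[JunctionLibrary] = None,
    z_threshold: float = 2.0,
    min_overlap: int = 10,
    min_supporting_reads: int = 1,
    hotspots: Optional[Mapping[str, frozenset[int]]] = None,
) -> tuple[list[ClassLabel], list[WntDriverProfile], list[FusionCall]]:
    """Full ground-truthing pipeline for one cohort: fusion detection,
    RSPO outlier calling on log-CPM, mutation interpretation, and class
    assignment.  Returns (labels, profiles, fusion calls)."""
    sample_ids = bundle.sample_ids
    fusion_calls: list[FusionCall] = []
    if bundle.reads and library is not None:
        for sid in sample_ids:
            for call in detect_fusions(
                bundle.reads.get(sid, []), library, min_overlap,
                min_supporting_reads,
            ):
                fusion_calls.append(
                    FusionCall(sid, call.fusion_id, call.gene, call.supporting_reads)
                )
    expr = bundle.expression
    norm = log_cpm(expr) if expr.space == "counts" else expr
    rspo_genes = [g for g in ("RSPO2", "RSPO3") if g in norm.values.index]
    outliers = zscore_outliers(norm, rspo_genes, threshold=z_threshold)
    rspo_high = call_rspo_high(outliers, fusion_calls)
    profiles = build_profiles(
        sample_ids, bundle.mutations, fusion_calls, rspo_high, hotspots
    )
    labels = [assign_class(p) for p in profiles]
    return labels, profiles, fusion_calls
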