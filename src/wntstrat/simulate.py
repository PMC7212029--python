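"""Synthetic multi-omic cohort generator with planted ground truth.

The generator draws, per sample, a Wnt class (ligand-dependent with
probability ``ld_fraction``, ligand-independent otherwise) and, for LD
samples, a driver subtype (RSPO fusion / stromal RSPO-high / RNF43
mutant).  It then plants the corresponding evidence in each omic layer:

* mutations — APC truncations or CTNNB1 hotspot missense for LI, RNF43
  frameshifts for LD-RNF43, silent passengers everywhere, and (rarely) a
  concurrent opposite-class driver;
* expression — class-conditional Gaussian log2 expression for the five
  Wnt negative regulators, a large RSPO2/3 shift for RSPO-driven samples,
  a fibroblast-signature shift for RSPO-high samples, then Poisson counts
  around a compositional mean with log-normal library sizes;
* methylation — logit-linear anticorrelated betas for AXIN2/NKD1 and
  CIMP-driven bimodal betas for NOTUM/APCDD1;
* reads — breakpoint-spanning junction reads plus decoy background reads
  for fusion-positive samples.

Each omic layer has its own RNG stream (seed + fixed offset) so adding or
removing one layer never perturbs another layer's draws; a fixed seed
gives bit-identical cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (
    CohortBundle,
    ExpressionMatrix,
    FastqRead,
    MethylationMatrix,
    MutationRecord,
    SampleAnnotation,
)
from .config import (
    CimpBimodal,
    FusionReadParams,
    LinearCoupled,
    SimulationConfig,
)
from .errors import ConfigError
from .fusions import JunctionLibrary, JunctionRecord

# Fixed stream offsets per data layer.
_STREAM_TRUTH = 0
_STREAM_MUTATIONS = 1
_STREAM_EXPRESSION = 2
_STREAM_METHYLATION = 3
_STREAM_READS = 4
_STREAM_LIBRARY = 5

SUBTYPES = ("RSPO_FUSION", "RSPO_HIGH", "RNF43")

#: CTNNB1 exon-3 phosphodegron codons treated as activating hotspots.
DEFAULT_CTNNB1_HOTSPOTS = frozenset({32, 33, 34, 35, 37, 41, 45})

_CMS_CHOICES = ("CMS1", "CMS2", "CMS3", "CMS4", "unknown")
_CMS_BASE_P = (0.13, 0.35, 0.13, 0.24, 0.15)


@dataclass
class TruthRecord:
    sample_id: str
    true_class: str  # LD | LI
    true_subtype: str  # RSPO_FUSION | RSPO_HIGH | RNF43 | none
    planted_drivers: frozenset[str]
    cimp: bool


@dataclass
class SyntheticTruth:
    """Planted per-sample ground truth against which recovery is tested."""

    records: list[TruthRecord]

    def classes(self) -> dict[str, str]:
        return {r.sample_id: r.true_class for r in self.records}

    def subtypes(self) -> dict[str, str]:
        return {r.sample_id: r.true_subtype for r in self.records}

    def cimp_flags(self) -> dict[str, bool]:
        return {r.sample_id: r.cimp for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "true_class": r.true_class,
                    "true_subtype": r.true_subtype,
                    "planted_drivers": ";".join(sorted(r.planted_drivers)),
                    "cimp": int(r.cimp),
                }
                for r in self.records
            ],
            columns=[
                "sample_id", "true_class", "true_subtype",
                "planted_drivers", "cimp",
            ],
        )


def _rng(config_seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(config_seed + offset)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def default_junction_library(
    seed: int, n_per_gene: int = 1, arm_length: int = 60
) -> JunctionLibrary:
    """Build a synthetic junction library: one (or more) made-up breakpoint
    sequence per RSPO gene, each a random upstream-partner arm joined to a
    random RSPO arm.  These sequences are synthetic stand-ins, not real
    fusion transcripts."""
    rng = _rng(seed, _STREAM_LIBRARY)
    junctions: dict[str, JunctionRecord] = {}
    for gene in ("RSPO2", "RSPO3"):
        for k in range(1, n_per_gene + 1):
            seq = _random_dna(rng, 2 * arm_length)
            junctions[f"FUS_{gene}_{k}"] = JunctionRecord(
                gene=gene, sequence=seq, breakpoint_offset=arm_length
            )
    return JunctionLibrary(junctions)


def simulate_junction_reads(
    sample_id: str,
    junction: JunctionRecord,
    params: FusionReadParams,
    seed: int,
    min_overlap: int = 10,
    reverse_complement_fraction: float = 0.0,
    fusion_tag: str = "junction",
) -> list[FastqRead]:
    """Emit junction-spanning reads plus background reads from a decoy.

    Every junction read covers at least ``min_overlap`` bases on each side
    of the breakpoint; background reads come from a random junction-free
    decoy sequence.  Qualities are constant.
    """
    L = params.read_length
    seq = junction.sequence
    if len(seq) < L:
        raise ConfigError(
            f"junction length {len(seq)} shorter than read_length {L}"
        )
    offset = junction.breakpoint_offset
    start_lo = max(0, offset + min_overlap - L)
    start_hi = min(offset - min_overlap, len(seq) - L)
    if start_hi < start_lo:
        raise ConfigError(
            f"no valid read placement spans the breakpoint of {fusion_tag} "
            f"with read_length={L}, min_overlap={min_overlap}"
        )
    rng = _rng(seed, _STREAM_READS)
    qual = "I" * L
    reads: list[FastqRead] = []
    for i in range(params.n_junction_reads):
        start = int(rng.integers(start_lo, start_hi + 1))
        fragment = seq[start : start + L]
        if rng.random() < reverse_complement_fraction:
            fragment = fragment.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        reads.append(FastqRead(f"{sample_id}/{fusion_tag}_{i}", fragment, qual))
    decoy = _random_dna(rng, max(2 * L, 200))
    for i in range(params.n_background_reads):
        start = int(rng.integers(0, len(decoy) - L + 1))
        reads.append(
            FastqRead(f"{sample_id}/bg_{i}", decoy[start : start + L], qual)
        )
    return reads


def theoretical_auc(config: SimulationConfig, gene: str) -> float:
    """Closed-form AUC of the two-Gaussian generating model for ``gene``:
    P(x_LI > x_LD) = Phi((mu_li - mu_ld) / sqrt(sigma_ld^2 + sigma_li^2))."""
    if gene not in config.class_effects:
        raise KeyError(f"gene {gene!r} has no class effect in this config")
    eff = config.class_effects[gene]
    spread = math.sqrt(2.0) * eff.sigma
    return float(norm.cdf((eff.mu_li - eff.mu_ld) / spread))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    config: SimulationConfig, with_reads: bool = True
) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate one cohort and its planted truth.  Deterministic in
    ``config.seed``.  ``with_reads=False`` skips FASTQ generation (the
    reads stream is still consumed identically, so all other layers are
    unchanged)."""
    config.validate()
    n = config.n_samples
    seed = config.seed
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    # ---- truth layer: class, subtype, CIMP, CMS --------------------------
    rng_truth = _rng(seed, _STREAM_TRUTH)
    is_ld = rng_truth.random(n) < config.ld_fraction
    subtype_idx = rng_truth.choice(
        3, size=n, p=list(config.ld_subtype_proportions)
    )
    cimp = rng_truth.random(n) < config.cimp_prevalence
    rspo_gene_choice = np.where(
        rng_truth.random(n) < config.rspo3_weight, "RSPO3", "RSPO2"
    )
    cms_draw = rng_truth.random(n)
    cms_pick = rng_truth.choice(_CMS_CHOICES, size=n, p=_CMS_BASE_P)

    subtypes = np.where(is_ld, np.array(SUBTYPES)[subtype_idx], "none")

    annotation: list[SampleAnnotation] = []
    for i, sid in enumerate(sample_ids):
        if subtypes[i] == "RSPO_HIGH" and cms_draw[i] < 0.8:
            cms = "CMS4"
        else:
            cms = str(cms_pick[i])
        annotation.append(
            SampleAnnotation(
                sample_id=sid,
                cohort="synthetic",
                cimp_status="positive" if cimp[i] else "negative",
                cms=cms,
            )
        )

    # ---- mutation layer ---------------------------------------------------
    rng_mut = _rng(seed, _STREAM_MUTATIONS)
    mutations: list[MutationRecord] = []
    planted: list[set[str]] = [set() for _ in range(n)]
    panel = config.panel
    for i, sid in enumerate(sample_ids):
        if is_ld[i]:
            if subtypes[i] == "RNF43":
                pos = int(rng_mut.integers(30, 700))
                mutations.append(
                    MutationRecord(sid, "RNF43", "frameshift", pos)
                )
                planted[i].add("rnf43_lof")
            elif subtypes[i] == "RSPO_FUSION":
                planted[i].add("rspo_fusion")
            else:
                planted[i].add("rspo_high")
            if rng_mut.random() < config.co_occurrence_rate:
                pos = int(rng_mut.integers(800, 1551))
                mutations.append(MutationRecord(sid, "APC", "nonsense", pos))
                planted[i].add("apc_lof")
        else:
            if rng_mut.random() < config.ctnnb1_fraction:
                pos = int(rng_mut.choice(sorted(DEFAULT_CTNNB1_HOTSPOTS)))
                mutations.append(MutationRecord(sid, "CTNNB1", "missense", pos))
                planted[i].add("ctnnb1_act")
            else:
                vclass = "nonsense" if rng_mut.random() < 0.6 else "frameshift"
                pos = int(rng_mut.integers(800, 1551))
                mutations.append(MutationRecord(sid, "APC", vclass, pos))
                planted[i].add("apc_lof")
            if rng_mut.random() < config.co_occurrence_rate:
                pos = int(rng_mut.integers(30, 700))
                mutations.append(MutationRecord(sid, "RNF43", "frameshift", pos))
                planted[i].add("rnf43_lof")
        n_passengers = rng_mut.poisson(config.passenger_rate)
        for _ in range(n_passengers):
            gene = str(rng_mut.choice(panel))
            pos = int(rng_mut.integers(1, 501))
            mutations.append(MutationRecord(sid, gene, "silent", pos))

    # ---- expression layer -------------------------------------------------
    rng_expr = _rng(seed, _STREAM_EXPRESSION)
    lo, hi = config.background_mu_range
    background_mu = rng_expr.uniform(lo, hi, size=config.n_background_genes)
    x = pd.DataFrame(0.0, index=panel, columns=sample_ids)
    mu_ld = np.array([e.mu_ld for e in config.class_effects.values()])
    mu_li = np.array([e.mu_li for e in config.class_effects.values()])
    sig = np.array([e.sigma for e in config.class_effects.values()])
    nr_genes = list(config.class_effects)
    class_mu = np.where(is_ld[None, :], mu_ld[:, None], mu_li[:, None])
    x.loc[nr_genes] = class_mu + rng_expr.standard_normal((len(nr_genes), n)) * sig[:, None]
    for gene, eff in config.rspo_effects.items():
        base = eff.mu_ld + rng_expr.standard_normal(n) * eff.sigma
        driven = (
            np.isin(subtypes, ("RSPO_FUSION", "RSPO_HIGH"))
            & (rspo_gene_choice == gene)
        )
        x.loc[gene] = base + np.where(driven, config.rspo_shift, 0.0)
    for gene in config.caf_genes:
        base = config.caf_baseline_mu + rng_expr.standard_normal(n) * config.caf_sigma
        x.loc[gene] = base + np.where(subtypes == "RSPO_HIGH", config.caf_shift, 0.0)
    for k, gene in enumerate(config.background_genes):
        x.loc[gene] = background_mu[k] + rng_expr.standard_normal(n) * config.background_sigma

    libsize = np.exp(
        config.library_size_log_mean
        + rng_expr.standard_normal(n) * config.library_size_log_sd
    )
    linear = np.exp2(x.to_numpy())
    frac = linear / linear.sum(axis=0, keepdims=True)
    lam = frac * libsize[None, :]
    counts = rng_expr.poisson(lam)
    expression = ExpressionMatrix(
        values=pd.DataFrame(counts, index=panel, columns=sample_ids, dtype=np.int64),
        space="counts",
    )

    # ---- methylation layer ------------------------------------------------
    rng_meth = _rng(seed, _STREAM_METHYLATION)
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    probe_genes: list[str] = []
    for gene, model in config.meth_models.items():
        if isinstance(model, LinearCoupled):
            signal = (
                model.a
                - model.b * x.loc[gene].to_numpy()
                + rng_meth.standard_normal(n) * model.s
            )
            for p in range(1, config.probes_per_gene + 1):
                logit = signal + rng_meth.standard_normal(n) * config.probe_jitter
                probe_rows.append(_invlogit(logit))
                probe_ids.append(f"{gene}_p{p}")
                probe_genes.append(gene)
        elif isinstance(model, CimpBimodal):
            centre = np.where(cimp, model.beta_high, model.beta_low)
            for p in range(1, config.probes_per_gene + 1):
                beta = centre + rng_meth.standard_normal(n) * model.s
                probe_rows.append(np.clip(beta, 0.0, 1.0))
                probe_ids.append(f"{gene}_p{p}")
                probe_genes.append(gene)
        else:  # pragma: no cover - guarded by config validation
            raise ConfigError(f"unknown methylation model for {gene}")
    methylation = None
    if probe_rows:
        beta = pd.DataFrame(
            np.vstack(probe_rows), index=probe_ids, columns=sample_ids
        )
        probe_map = pd.Series(probe_genes, index=pd.Index(probe_ids, name="probe"),
                              name="gene")
        methylation = MethylationMatrix(beta=beta, probe_map=probe_map)

    # ---- reads layer ------------------------------------------------------
    reads: dict[str, list[FastqRead]] = {}
    if with_reads:
        library = default_junction_library(seed)
        fusion_ids = {
            gene: next(
                fid for fid in sorted(library.junctions)
                if library[fid].gene == gene
            )
            for gene in ("RSPO2", "RSPO3")
        }
        rng_reads = _rng(seed, _STREAM_READS)
        for i, sid in enumerate(sample_ids):
            read_seed = int(rng_reads.integers(0, 2**31 - 100))
            if subtypes[i] == "RSPO_FUSION":
                fid = fusion_ids[str(rspo_gene_choice[i])]
                reads[sid] = simulate_junction_reads(
                    sid,
                    library[fid],
                    config.fusion_read_params,
                    seed=read_seed,
                    min_overlap=config.min_overlap,
                    reverse_complement_fraction=0.5,
                    fusion_tag=fid,
                )
            else:
                params = FusionReadParams(
                    read_length=config.fusion_read_params.read_length,
                    n_junction_reads=0,
                    n_background_reads=config.fusion_read_params.n_background_reads,
                )
                reads[sid] = simulate_junction_reads(
                    sid,
                    library[fusion_ids["RSPO3"]],
                    params,
                    seed=read_seed,
                    min_overlap=config.min_overlap,
                )

    truth = SyntheticTruth(
        records=[
            TruthRecord(
                sample_id=sid,
                true_class="LD" if is_ld[i] else "LI",
                true_subtype=str(subtypes[i]),
                planted_drivers=frozenset(planted[i]),
                cimp=bool(cimp[i]),
            )
            for i, sid in enumerate(sample_ids)
        ]
    )
    bundle = CohortBundle(
        annotation=annotation,
        mutations=mutations,
        expression=expression,
        methylation=methylation,
        reads=reads if with_reads else None,
    )
    return bundle, truth
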