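"""Simulation configuration: the generating model for synthetic cohorts.

The defaults describe a colorectal cohort in which ~11.3% of tumours carry
a ligand-dependent (LD) Wnt driver — split between RSPO2/3 fusions,
stromal RSPO-high tumours and RNF43-mutant tumours — and the remainder are
ligand-independent (LI, APC or CTNNB1 driven).  Five Wnt negative-regulator
genes are expressed higher in LI than LD tumours on the log2 scale;
methylation of AXIN2/NKD1 is linearly coupled (anticorrelated) to their
expression, while NOTUM/APCDD1 methylation is bimodal and driven by CIMP
status.  Everything is overridable from YAML.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClassEffect:
    """Class-conditional Gaussian log2-expression for one gene."""

    mu_ld: float
    mu_li: float
    sigma: float


@dataclass(frozen=True)
class LinearCoupled:
    """Methylation model: logit(beta) = a - b * log2_expression + N(0, s)."""

    a: float
    b: float
    s: float


@dataclass(frozen=True)
class CimpBimodal:
    """Methylation model: beta centred at beta_high when the sample is
    CIMP-positive, beta_low otherwise, with Gaussian noise s, clipped."""

    beta_low: float
    beta_high: float
    s: float


MethModel = Union[LinearCoupled, CimpBimodal]


@dataclass(frozen=True)
class FusionReadParams:
    read_length: int = 50
    n_junction_reads: int = 8
    n_background_reads: int = 20


def mixture_sd(effect: ClassEffect, ld_fraction: float) -> float:
    """Marginal SD of a gene's log2 expression under the two-class mixture."""
    f = ld_fraction
    return math.sqrt(
        effect.sigma**2 + f * (1.0 - f) * (effect.mu_li - effect.mu_ld) ** 2
    )


def linear_coupling_noise(
    b: float,
    sd_expr: float,
    target_r: float,
    probe_jitter: float = 0.0,
    probes_per_gene: int = 1,
) -> float:
    """Sample-level logit-scale noise s giving Pearson correlation
    ``target_r`` between gene-level mean beta and log2 expression, in the
    quasi-linear regime of the inverse logit.

    On the logit scale, corr = b*sd_expr / sqrt(b^2 sd_expr^2 + s_tot^2)
    where s_tot^2 = s^2 + probe_jitter^2 / probes_per_gene (probe jitter is
    averaged down by the per-gene probe mean).  Solve for s.
    """
    r = abs(target_r)
    if not 0 < r < 1:
        raise ConfigError("target_r must be in (0, 1)")
    s_tot_sq = (b * sd_expr) ** 2 * (1.0 / r**2 - 1.0)
    s_sq = s_tot_sq - probe_jitter**2 / probes_per_gene
    if s_sq <= 0:
        raise ConfigError(
            "probe jitter alone exceeds the noise budget for the target r"
        )
    return math.sqrt(s_sq)


#: Cancer-associated fibroblast marker genes scored as the stromal signature.
DEFAULT_CAF_GENES = (
    "FAP", "PDGFRB", "ACTA2", "THY1", "COL1A1", "COL1A2", "PDPN", "ZEB1",
)

DEFAULT_CLASS_EFFECTS = {
    "AXIN2": ClassEffect(mu_ld=4.2, mu_li=6.3, sigma=0.8),
    "NKD1": ClassEffect(mu_ld=4.5, mu_li=6.0, sigma=0.9),
    "APCDD1": ClassEffect(mu_ld=5.0, mu_li=6.1, sigma=0.9),
    "NOTUM": ClassEffect(mu_ld=3.6, mu_li=5.2, sigma=1.1),
    "DKK4": ClassEffect(mu_ld=2.4, mu_li=3.9, sigma=1.2),
}

#: Baseline (unshifted) RSPO expression; fusion / RSPO-high samples add
#: ``rspo_shift`` log2 units to their driving RSPO gene.
DEFAULT_RSPO_EFFECTS = {
    "RSPO2": ClassEffect(mu_ld=3.0, mu_li=3.0, sigma=0.5),
    "RSPO3": ClassEffect(mu_ld=3.2, mu_li=3.2, sigma=0.5),
}


def _default_meth_models(
    class_effects: dict[str, ClassEffect],
    ld_fraction: float,
    probe_jitter: float,
    probes_per_gene: int,
    target_r: float = -0.7,
) -> dict[str, MethModel]:
    models: dict[str, MethModel] = {}
    for gene in ("AXIN2", "NKD1"):
        if gene not in class_effects:
            continue
        eff = class_effects[gene]
        b = 0.3
        sd = mixture_sd(eff, ld_fraction)
        s = linear_coupling_noise(b, sd, target_r, probe_jitter, probes_per_gene)
        mean_x = (1.0 - ld_fraction) * eff.mu_li + ld_fraction * eff.mu_ld
        models[gene] = LinearCoupled(a=b * mean_x, b=b, s=s)
    for gene in ("NOTUM", "APCDD1"):
        if gene in class_effects:
            models[gene] = CimpBimodal(beta_low=0.2, beta_high=0.7, s=0.05)
    return models


@dataclass
class SimulationConfig:
    """Full generating model for one synthetic cohort."""

    n_samples: int = 600
    ld_fraction: float = 0.113
    # (rspo_fusion, rspo_high, rnf43)
    ld_subtype_proportions: tuple[float, float, float] = (0.45, 0.20, 0.35)
    co_occurrence_rate: float = 0.02
    ctnnb1_fraction: float = 0.10  # LI drivers that are CTNNB1 hotspots, not APC
    passenger_rate: float = 1.0  # mean silent passenger mutations per sample
    class_effects: dict[str, ClassEffect] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    rspo_effects: dict[str, ClassEffect] = field(
        default_factory=lambda: dict(DEFAULT_RSPO_EFFECTS)
    )
    rspo_shift: float = 6.0  # log2 shift for the driving RSPO gene
    rspo3_weight: float = 0.65  # fraction of RSPO-driven samples on RSPO3
    caf_genes: tuple[str, ...] = DEFAULT_CAF_GENES
    caf_baseline_mu: float = 5.0
    caf_sigma: float = 0.8
    caf_shift: float = 1.5  # extra stromal signal in RSPO-high tumours
    n_background_genes: int = 45
    background_mu_range: tuple[float, float] = (3.0, 8.0)
    background_sigma: float = 1.0
    library_size_log_mean: float = math.log(5e6)
    library_size_log_sd: float = 0.15
    meth_models: dict[str, MethModel] = field(default_factory=dict)
    probes_per_gene: int = 3
    probe_jitter: float = 0.08  # probe-specific logit-scale noise
    cimp_prevalence: float = 0.25
    fusion_read_params: FusionReadParams = field(default_factory=FusionReadParams)
    min_overlap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()
        if not self.meth_models:
            self.meth_models = _default_meth_models(
                self.class_effects,
                self.ld_fraction,
                self.probe_jitter,
                self.probes_per_gene,
            )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {value}")

        if self.n_samples < 0:
            raise ConfigError(f"n_samples must be >= 0, got {self.n_samples}")
        _prob("ld_fraction", self.ld_fraction)
        _prob("co_occurrence_rate", self.co_occurrence_rate)
        _prob("ctnnb1_fraction", self.ctnnb1_fraction)
        _prob("cimp_prevalence", self.cimp_prevalence)
        _prob("rspo3_weight", self.rspo3_weight)
        props = self.ld_subtype_proportions
        if len(props) != 3 or any(p < 0 for p in props):
            raise ConfigError("ld_subtype_proportions must be 3 nonnegative values")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError(
                f"ld_subtype_proportions must sum to 1, got {sum(props)}"
            )
        for gene, eff in {**self.class_effects, **self.rspo_effects}.items():
            if eff.sigma <= 0:
                raise ConfigError(f"sigma for {gene} must be > 0")
        if self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene must be >= 1")
        rp = self.fusion_read_params
        if rp.read_length < 2 * self.min_overlap:
            raise ConfigError(
                "read_length must be >= 2 * min_overlap "
                f"({rp.read_length} < {2 * self.min_overlap})"
            )

    # -- panel --------------------------------------------------------------
    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i:03d}" for i in range(1, self.n_background_genes + 1)]

    @property
    def panel(self) -> list[str]:
        """Ordered gene panel: negative regulators, RSPO genes, CAF
        signature, then background genes."""
        return (
            list(self.class_effects)
            + list(self.rspo_effects)
            + list(self.caf_genes)
            + self.background_genes
        )

    # -- YAML ---------------------------------------------------------------
    def to_dict(self) -> dict:
        out = asdict(self)
        out["schema_version"] = SCHEMA_VERSION
        out["class_effects"] = {
            g: list(asdict(e).values()) for g, e in self.class_effects.items()
        }
        out["rspo_effects"] = {
            g: list(asdict(e).values()) for g, e in self.rspo_effects.items()
        }
        meth = {}
        for g, m in self.meth_models.items():
            kind = "linear_coupled" if isinstance(m, LinearCoupled) else "cimp_bimodal"
            meth[g] = {"kind": kind, **asdict(m)}
        out["meth_models"] = meth
        out["fusion_read_params"] = asdict(self.fusion_read_params)
        out["caf_genes"] = list(self.caf_genes)
        out["ld_subtype_proportions"] = list(self.ld_subtype_proportions)
        out["background_mu_range"] = list(self.background_mu_range)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema_version {version}")
        if "class_effects" in raw:
            raw["class_effects"] = {
                g: ClassEffect(*v) for g, v in raw["class_effects"].items()
            }
        if "rspo_effects" in raw:
            raw["rspo_effects"] = {
                g: ClassEffect(*v) for g, v in raw["rspo_effects"].items()
            }
        if "meth_models" in raw:
            models: dict[str, MethModel] = {}
            for g, spec in raw["meth_models"].items():
                spec = dict(spec)
                kind = spec.pop("kind")
                if kind == "linear_coupled":
                    models[g] = LinearCoupled(**spec)
                elif kind == "cimp_bimodal":
                    models[g] = CimpBimodal(**spec)
                else:
                    raise ConfigError(f"unknown methylation model kind {kind!r}")
            raw["meth_models"] = models
        if "fusion_read_params" in raw:
            raw["fusion_read_params"] = FusionReadParams(**raw["fusion_read_params"])
        for key in ("ld_subtype_proportions", "background_mu_range", "caf_genes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def replace_config(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Return a copy of ``config`` with fields replaced (re-validated).

    Methylation models are re-derived from the new class effects unless the
    caller supplies them explicitly, so the coupling targets stay honest
    after an effect-size change.
    """
    raw = config.to_dict()
    raw_overrides = {}
    for key, value in overrides.items():
        raw_overrides[key] = value
    base = SimulationConfig.from_dict(raw)
    data = base.__dict__ | raw_overrides
    if "meth_models" not in overrides:
        data = dict(data)
        data["meth_models"] = {}
    cfg = SimulationConfig.__new__(SimulationConfig)
    for key, value in data.items():
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg
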