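# Methods

## Problem and model

Colorectal tumours activate Wnt signalling through two mutually exclusive
routes. *Ligand-independent* (LI) tumours mutate the intracellular
machinery — truncating APC or stabilising β-catenin through CTNNB1
exon-3 hotspot missense mutations — and no longer require Wnt ligand.
*Ligand-dependent* (LD) tumours disrupt the R-Spondin axis (RNF43 loss,
RSPO2/3 gene fusions, or stromal RSPO overexpression) and amplify
endogenous ligand signalling, which keeps them sensitive to ligand
inhibition (Porcupine inhibitors). Because intact Wnt negative-feedback
regulators (AXIN2, NKD1, APCDD1, NOTUM, DKK4) would restrain LD — but not
LI — signalling, LD tumours selectively silence them, partly through
promoter methylation. Low AXIN2 expression is therefore an actionable
single-gene biomarker for LD status.

The package implements this chain end to end on synthetic cohorts:

1. **Ground truth.** Per sample, driver evidence is collected as five
   boolean flags. APC/RNF43 variants count as loss of function when their
   class is nonsense, frameshift or splice-site; CTNNB1 missense counts
   as activating at the configurable hotspot codons {32, 33, 34, 35, 37,
   41, 45} (the exon-3 phosphodegron; the set is a documented stand-in,
   configurable because functional-relevance filters differ between
   curation pipelines). RSPO fusions are detected from reads (below);
   RSPO-high status is an RSPO2/3 log-CPM z-score ≥ 2 (cohort-relative,
   sample SD with n−1) without a fusion call. LI evidence = apc ∨ ctnnb1;
   LD evidence = rnf43 ∨ fusion ∨ rspo-high. Both → EX ("concurrent"),
   neither → EX ("no driver"); pure LD with >1 flag keeps the LD label
   with subtype AMBIGUOUS.
2. **Fusion detection.** A read supports a junction iff it (or its
   reverse complement) contains, as an exact substring, the window of
   `min_overlap` = 10 bases each side of the breakpoint. Exact matching is
   deliberate: the synthetic reads are error-free and a random 20-mer hit
   in decoy sequence has probability ≈ L·4⁻²⁰ per read. There is no
   mismatch-tolerant mode.
3. **Expression.** log-CPM is log2(1 + 1e6·c/libsize) (`prior_count`
   exposed); zero maps exactly to zero and the transform is scale
   invariant per sample. Differential expression is a per-gene Welch t
   (LI − LD orientation) with Benjamini–Hochberg adjustment over exactly
   the tested genes. Welch was chosen over a moderated t as a
   self-contained, exactly testable stand-in adequate at the simulated
   group sizes. Genes with zero variance in both groups are reported with
   t=0, p=1 and a degenerate flag rather than dropped.
4. **Enrichment.** Weighted Kolmogorov–Smirnov running sum over genes
   ranked by Welch t (descending, ties by symbol): hits add
   |t|^α/N_R (α=1), misses subtract 1/(N−N_hits); the ES is the extremum
   of maximal absolute deviation (first occurrence on ties, clipped into
   [−1,1]; the all-hit case returns exactly 1). Significance by phenotype
   permutation — labels reshuffled, ranking recomputed — which preserves
   inter-gene correlation. p_nominal uses a +1 pseudo-count over same-sign
   permutations; NES divides ES by the mean |ES| of same-sign permutations
   and is reported as undefined (None) below 10 same-sign permutations
   instead of dividing by a noisy mean. NES magnitudes are therefore not
   comparable across implementations with different ranking metrics.
5. **Methylation.** Gene-level beta is the unweighted mean over mapped
   probes. Differential methylation is Welch on beta values per probe
   (direction *hyper* = higher in LD), BH over all probes. CIMP-stratified
   comparisons report group means and Welch p per (gene, class); strata
   with <2 samples are marked not-testable, never silently dropped.
   Methylation–expression coupling is the Pearson r between gene-level
   mean beta and log-CPM with the t-transform p on n−2 df.
6. **Biomarker.** Positive class is LD; the decision score is low
   expression (call LD when x < τ). The AUC is pairwise concordance
   P(x_LI > x_LD) + ½P(=), computed from midranks; the trapezoidal area
   over the ROC equals it to 1e-12 (property-tested). Candidate
   thresholds are midpoints between consecutive distinct scores plus ±∞
   sentinels, making the rule well defined off the training grid; τ
   maximises sensitivity + specificity with ties broken by higher
   specificity, then lower τ. The AUC interval is a stratified percentile
   bootstrap (default B=2000), exactly reproducible under a seed. EX
   samples never enter fitting or the confusion matrix but are always
   reported with their scores.

## Synthetic cohort generator

The generator's defaults describe the study conditions; every parameter
is overridable from YAML (schema_version 1) and all stochastic layers are
seeded.

| parameter | default | meaning |
|---|---|---|
| n_samples | 600 | cohort size |
| ld_fraction | 0.113 | LD prevalence |
| ld_subtype_proportions | 0.45 / 0.20 / 0.35 | RSPO-fusion / RSPO-high / RNF43 |
| co_occurrence_rate | 0.02 | chance of an added opposite-class driver |
| AXIN2 (mu_ld, mu_li, sigma) | 4.2, 6.3, 0.8 | log2 class-conditional expression |
| rspo_shift | 6.0 log2 | RSPO2/3 shift in RSPO-driven samples |
| RSPO2/3 baseline sigma | 0.5 | log2 |
| caf_shift | 1.5 | fibroblast-signature shift in RSPO-high samples |
| probes_per_gene / probe_jitter | 3 / 0.08 | methylation probes and logit-scale probe noise |
| cimp_prevalence | 0.25 | CIMP-positive fraction |
| library size | lognormal(log 5e6, 0.15) | sequencing depth |
| fusion reads | 50 bp, 8 junction + 20 background | per fusion-positive sample |

The five negative regulators get class-conditional Gaussian log2
expression; AXIN2's defaults give a closed-form two-Gaussian AUC
Φ(2.1/(0.8·√2)) ≈ 0.968, inside the validation range a clinical-grade
marker should reach. The paper-adjacent effect sizes for the other NR
genes (NKD1 1.5, APCDD1 1.1, NOTUM 1.6, DKK4 1.5 log2 units) are
calibration choices, not estimates of any real dataset. Counts are
Poisson around a compositional mean with log-normal library sizes:
downstream analyses operate on log-CPM, where the Gaussian structure is
the tested quantity; negative-binomial overdispersion is intentionally
omitted. The RSPO shift (+6 log2, baseline σ=0.5) is set so the z≥2
outlier rule separates planted RSPO-driven samples from the baseline
with ≈5σ margin on both sides under the inflated cohort SD — chosen from
these closed-form margins so that exact recovery at n=600 is a property
of the generating model, not luck.

Methylation for AXIN2/NKD1 follows logit(beta) = a − b·x + N(0, s) per
sample (b=0.3, a centred at the mixture mean so betas stay in the
quasi-linear mid-range of the inverse logit), plus per-probe N(0, 0.08)
jitter; s is derived in closed form so the generating-model correlation
between gene-level mean beta and expression is −0.7:
s² = (b·sd_x)²(1/r² − 1) − jitter²/P, with sd_x the class-mixture SD
(`linear_coupling_noise`). NOTUM/APCDD1 betas are bimodal at 0.2/0.7
(noise 0.05) driven solely by the CIMP flag, which is drawn independently
of everything else. Each omic layer consumes its own RNG stream
(seed + fixed offset), so adding or removing a layer never perturbs the
others and a fixed seed gives byte-identical output files.

What the generator does **not** emulate: full-transcriptome dimension
(the panel is 60 genes: 5 NR + 2 RSPO + 8 CAF + 45 background),
sequencing error, batch effects, copy number, overdispersion beyond
Poisson, within-gene probe heterogeneity beyond i.i.d. jitter, or any
dependence between mutation burden and expression. Passing tests
therefore demonstrate internal consistency of the statistical machinery
under the stated generating model, not performance on real tumours.

## Numerical choices and degenerate inputs

- Tie-breaks are deterministic everywhere: gene symbol (ranking), first
  occurrence (ES peak), higher specificity then lower τ (threshold).
- Zero-variance genes: hard error where a z-score is meaningless
  (outlier calling, signature scoring, correlation), flagged-but-reported
  where a test statistic has a natural null value (DE, DMP: t=0, p=1).
- Empty cohorts, empty read sets and empty mutation tables are valid
  inputs returning empty outputs; configuration violations raise a
  ConfigError naming the field.
- Expression-matrix round trips are exact for counts and to 12
  significant digits for normalised values (`%.12g` formatting).
- Bootstrap intervals are clamped to contain the point estimate.

## Problem sizes used by the test and acceptance runs

The suite runs the oracle-equivalence checks at 300–500 random instances
each; recovery and calibration checks use n=600 cohorts (10–25 seeds),
n=440 for methylation coupling (20–100 seeds), n=120–200 for the null
calibrations (20–50 seeds), with 200–1000 permutations per GSEA call.
These sizes put every Monte-Carlo assertion several standard errors away
from its pass boundary. The full default suite completes in well under
five minutes on one CPU.

## Known limitations

- The curated Wnt target gene subsets are placeholders over background
  genes (only the negative-regulator set is real); user-supplied GMT
  files are accepted anywhere a set collection is consumed.
- The fusion detector requires exact junction matches and a known
  junction library; it does not discover novel breakpoints or align
  reads.
- Thresholds are cohort-specific: transfer across cohorts is meaningful
  only between matrices declared in the same expression space.
- NES values depend on the ranking metric and permutation scheme and are
  not comparable to other GSEA implementations.
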