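# wntstrat

Molecular stratification of colorectal tumours into Wnt
**ligand-dependent (LD)** and **ligand-independent (LI)** classes, and
derivation of a single-gene *AXIN2* expression biomarker for the LD
group — the tumours that remain sensitive to Wnt ligand inhibition
(Porcupine inhibitors) and can be stratified to such trials at
diagnosis.

The package is written for computational biologists who want a tested,
fully synthetic, end-to-end implementation of this stratification
pipeline: a multi-omic cohort simulator with planted ground truth, and
every analysis stage needed to recover that truth and quantify the
biomarker.

## What it computes

- **Ground truth** per sample from mutations and reads: APC truncation /
  CTNNB1 exon-3 hotspot missense → LI driver; RNF43 truncation, RSPO2/3
  fusion (breakpoint-spanning reads) or fusion-negative RSPO outlier
  expression (z ≥ 2) → LD driver. Concurrent or absent drivers → EX,
  excluded from class comparisons but always reported.
- **Differential expression** (Welch t on log-CPM, BH-corrected) and
  **gene-set enrichment** (weighted Kolmogorov–Smirnov running sum,
  phenotype-permutation NES and nominal p, leading edge) of the Wnt
  negative regulators *AXIN2, NKD1, APCDD1, NOTUM, DKK4* — all higher in
  LI tumours, where feedback is functionally redundant.
- **Methylation**: per-probe differential methylation (LD-hyper),
  CIMP-stratified comparisons (AXIN2/NKD1 methylation is
  CIMP-independent; NOTUM/APCDD1 is CIMP-driven), and the near-linear
  methylation–expression anticorrelation (r ≈ −0.7).
- **Biomarker**: ROC of low *AXIN2* log-CPM as an LD classifier. The AUC
  is pairwise concordance P(x_LI > x_LD) + ½P(=); for the default
  generating model it has the closed form Φ((μ_LI−μ_LD)/(σ√2)) =
  Φ(2.1/(0.8·√2)) ≈ 0.968. The operating threshold τ maximises
  sensitivity + specificity; the AUC CI is a stratified percentile
  bootstrap.

See `docs/methods.md` for the model, all defaults and their rationale.

## Worked example

Run the numbered analysis scripts in order (each prints what it found
and writes small tables under `results/`; the large cohort itself lives
under `scratch/`):

```sh
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_classify_drivers.py
python analysis/03_differential_expression.py
python analysis/04_gsea.py
python analysis/05_methylation.py
python analysis/06_biomarker.py
```

With seed 7 the classification stage prints

```
labels: {'LD': 56, 'LI': 533, 'EX': 11} (26 fusion calls)
driver burden: {'0': 0, '1': 589, '>=2': 11}
planted-class agreement: 589/600
```

— 56 of 600 tumours are called ligand-dependent, drivers are mutually
exclusive in 589/600 samples, and the 11 EX samples are exactly the
planted concurrent-driver cases. Differential expression then finds all
five negative regulators significantly higher in LI (AXIN2 mean
difference 2.11 log2, q ≈ 5e-26), GSEA gives the negative-regulator set
ES = 1.00 with nominal p = 0.002 while the placeholder target sets stay
null, methylation shows 6/6 significant probes hypermethylated in LD
with AXIN2 coupling r = −0.68 (CIMP-independent, while NOTUM/APCDD1
track CIMP status), and the biomarker stage reports

```
AXIN2 AUC 0.9619 (95% CI 0.9353-0.9829), n_LD=56, n_LI=533
threshold 12.5326 log-CPM -> sensitivity 92.9%, specificity 91.6%
EX tumours (n=11) show variable AXIN2 expression: 11.98-14.85 log-CPM
```

— the empirical AUC sits near the generating model's closed-form 0.968,
and the selected cutpoint recovers LD tumours from expression alone.

The same pipeline is available as a CLI (`wntstrat simulate /
detect-fusions / classify / expression / gsea / methylation / biomarker`),
and `wntstrat full --seed 7 --out-dir out/` chains every stage and writes
a deterministic `out/report.json`.

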