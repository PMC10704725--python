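# transsig

Pipeline for deriving and applying an epithelial **IL-6 trans-signaling
gene signature**.  IL-6 signals *classically* through membrane IL-6Rα, and
in *trans* when complexed with the soluble receptor (sIL-6Rα) on cells —
like airway epithelium — that lack the membrane receptor.  The analysis this
package implements asks three questions about that distinction:

1. **Does sIL-6Rα change what IL-6 does, or just how much?**  Donor-adjusted
   negative-binomial differential expression of stimulated airway epithelial
   cultures, an OLS fit of trans on classic log2 fold changes
   (`y = slope·x + b`; the planted multiplier is 1.2), and an
   IL-6 × sIL-6Rα interaction test that is null when trans-signaling is pure
   amplification.
2. **Which genes make a usable signature?**  Three filters over the
   significant up-regulated trans-response genes: highest baseline-expression
   quartile + top 5% by fold change → GSEA core enrichment (leading edge) in
   every validation dataset → exclusion of IL-4/IL-13-sensitive (Th2) genes.
3. **What does the signature say about patients?**  Per-sample signature
   Z-scores (mean per-gene z of log2 expression), GSEA of the signature in
   disease vs control cohorts, quartile stratification, and a Mann–Whitney
   comparison of clinical phenotypes between signature-high and -low
   quartiles.

The study's raw data are not publicly deposited, so a synthetic-data module
generates stimulation experiments (negative-binomial counts, donor effects,
planted amplification, inhibitor blockade) and patient cohorts (planted
signature-high subgroup, a negative score→sputum-eosinophil link) together
with ground truth; tests and benchmarks are recovery and calibration
statements against that truth.  See `docs/methods.md` for the model and all
conventions.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on simulated
data (all accept `--seed`):

```bash
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_amplification_and_interaction.py --seed 1
python analysis/04_derive_signature.py --seed 1
python analysis/05_cohort_enrichment.py --seed 1
python analysis/06_phenotype_comparison.py --seed 1
```

Output of steps 02–04 at seed 1:

```
                     il6 vs control:   234 DEGs (q<0.05), 111 up
                   sil6r vs control:     2 DEGs (q<0.05), 1 up
               il6_sil6r vs control:   380 DEGs (q<0.05), 189 up
    il6_sil6r_olamkicept vs control:     0 DEGs (q<0.05), 0 up
   il6_sil6r_tocilizumab vs control:     2 DEGs (q<0.05), 1 up

amplification fit over 396 significant genes: y = 1.146 x + -0.0176
interaction test at multiplier 1.0: 1 genes at q<0.05 (of 9951)

signature (5 genes): S100A9, SERPINB1, LRG1, IFITM3, CLCA2
planted truth recovered exactly: True
```

Reading this: IL-6 alone regulates a few hundred genes, the combination
regulates more (the planted 1.2× amplification), the soluble receptor alone
and the trans-selective blocker Olamkicept regulate essentially nothing, and
Tocilizumab leaves only a residual.  The fitted slope 1.15 recovers the
planted multiplier within the benchmark tolerance (±0.1), and with the
multiplier forced to 1.0 the interaction test is empty — amplification, not
a qualitatively different program.  The derivation then returns exactly the
five planted signature genes while rejecting the four decoys that each fail
one filter.

Step 05/06 score a simulated 77-asthma / 66-control cohort, stratify the
asthma patients into score quartiles (19/20/19/19), and compare phenotypes
between the extreme quartiles.  Enrichment and phenotype p-values vary
across cohort realizations by design — the planted shift is detected in
roughly four of five seeds (seed 1 happens to be a weaker draw at
p ≈ 0.07; the replicate behavior is quantified in `tests/test_acceptance.py`
and `docs/methods.md`); the sputum-eosinophil comparison shows the planted
negative direction (lower eosinophils in signature-high patients).

The same stages are available as a CLI (`transsig simulate-experiment`,
`de`, `amplification-fit`, `derive-signature`, `score`, `enrich`,
`compare-phenotypes`; see `transsig --help`) and as plain library functions
(`import transsig`).

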