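# timeprofiler

Tumor immune microenvironment (TIME) profiling from bulk expression:
z-score-based subtype classification, mutation-enrichment screening,
glycolysis/OXPHOS metabolic phenotyping, survival comparison, and paired
perturbation (inhibitor-response) analysis — with a synthetic multi-omic
cohort generator so every stage can be tested against planted ground truth.

It is aimed at computational tumor-immunology analyses of TCGA/cBioPortal-style
exports: a gene × sample expression matrix, a MAF-subset mutation table, and a
per-sample clinical table.

## The model

Everything operates on per-gene cohort z-scores,
`z = (x − mean_gene) / sd_gene` (population sd over the full analyzed
cohort). On that scale:

* **TIME subtypes** are conjunctive directional rules over immune markers
  (CD45/PTPRC, CD8A, FOXP3, CD79A, CD68, GZMB, PRF1, S100A9):
  *immune-activated* = cytotoxic-response genes (PTPRC, CD8A, GZMB, PRF1)
  all `z > 0`; *immune-suppressed* = cytotoxic genes down with CD68 and
  S100A9 up; *immune-absent* = all eight markers down. A sample must satisfy
  exactly one rule; everything else — in practice the majority — is
  *unclassified*.
* **Cytolytic activity (CytAct)** is the joint call on granzyme B and
  perforin: `up` iff both `z > 0`, `down` iff both `z < 0`.
* **Mutation enrichment** filters genes to ≥ 10 mutation records, then tests
  patient-level mutation status × subtype on a 2×3 table with the
  Freeman–Halton exact test (exhaustive enumeration, point-probability
  two-sided rule), plus pairwise 2×2 Fisher follow-ups and BH q-values.
* **Metabolic phenotype** scores a 24-gene glycolysis and a 31-gene OXPHOS
  panel by per-gene *upregulation frequency* (fraction of stratum samples
  with `z > 0`) inside regulator-high/low expression strata (`|z| ≥ 1`),
  with per-gene Fisher tests, Welch panel-level t-tests, and share-normalized
  relative phenotypes.
* **Survival** uses the Kaplan–Meier product-limit estimator and Gehan's
  generalized Wilcoxon test
  `X² = [Σ n_i (d_iA − e_iA)]² / Σ n_i² v_iA ~ χ²(1)`
  comparing activated vs pooled suppressed+absent tumors.
* **Perturbation response** pairs control/treated replicate means *by gene*
  and tests a panel's shift with a paired two-sided t-test.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_classify_time_subtypes.py
```

prints, for the default 530-sample synthetic cohort:

```
planted subtype counts: {'unclassified': 368, 'absent': 110, 'suppressed': 32, 'activated': 20}
assigned counts: {'unclassified': 340, 'absent': 98, 'activated': 61, 'suppressed': 31}
recovery of planted activated/suppressed/absent labels: 92.0%
HPV-positive share by subtype:
     activated: 18/61 = 30%
    suppressed: 5/31 = 16%
        absent: 6/98 = 6%
```

92% of the planted activated/suppressed/absent labels are recovered after
cohort re-standardization; the HPV gradient across subtypes mirrors the
planted per-subtype HPV rates. Continuing,

```bash
python analysis/05_metabolic_phenotype.py
```

```
glycolysis: mean up-fraction high=0.969 low=0.029, Welch t=191.78, p=1.93e-65
oxphos: mean up-fraction high=0.033 low=0.975, Welch t=-207.18, p=2.37e-87
stratum  glycolysis_share  oxphos_share
   high             0.967         0.033
    low             0.029         0.971
```

i.e. regulator-high tumors are glycolysis-dominant and regulator-low tumors
OXPHOS-dominant, recovering the planted coupling (ρ = 0.8). Scripts 03, 04
and 06 run the survival comparison, the mutation-enrichment screen, and the
cell-line perturbation analysis the same way; all outputs land under
`results/`. The same stages are available as a CLI
(`timeprofiler --workdir RUN simulate|classify|enrich|metabolize|survive|perturb|report`)
or as one call via `timeprofiler.pipeline.run_pipeline`.

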