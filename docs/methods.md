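# Methods

## Scope and data model

`timeprofiler` implements a cohort-level immunogenomic analysis over three
tab-delimited inputs: a gene × sample expression matrix (assumed already
normalized; cBioPortal export dialect), a MAF-subset mutation table
(`Tumor_Sample_Barcode`, `Hugo_Symbol`, `Variant_Classification`), and a
per-sample clinical table with HPV status, site, stage and OS/DFS endpoints.
Gene symbols are matched case-sensitively after an alias map
(CD45→PTPRC, GLUT1→SLC2A1, Perforin/PFN1→PRF1, Granzyme→GZMB), because
immunopathology marker names and HGNC symbols are used interchangeably in
practice.

## z-scoring

All classification rules operate on per-gene z-scores with the **full
analyzed cohort** as reference population and **population sd (`ddof=0`)**;
no holdout or external reference is involved, and `ddof` is configurable.
Zero-variance genes carry no directional information and are mapped to an
all-zero row (never "up" or "down") and recorded in `degenerate_genes`
rather than raising: panels containing a constant gene stay usable and the
affected sample calls simply fail the strict inequalities. A single-sample
matrix is rejected (sd undefined for classification purposes). z-scoring is
idempotent to 1e-9 for nondegenerate genes.

## Subtype rules

A subtype panel is a set of (gene, direction) pairs with threshold τ
(default 0). Satisfaction is a **strict conjunction**: every up-gene must
have z > τ and every down-gene z < τ; z exactly at τ fails both directions,
since the cohort mean is deliberately unassignable. A sample is labelled iff
it satisfies exactly one of the three panels; zero or multiple hits (the
latter impossible for the shipped rules, which demand opposite GZMB
directions) yield `unclassified`. The conjunctive reading — rather than a
composite mean score — is what produces the heavy exclusion characteristic
of this design; a `mean` mode is available for sensitivity analysis. The
shipped panels (activated = PTPRC, CD8A, GZMB, PRF1 up; suppressed = CD8A,
GZMB, PRF1 down + CD68, S100A9 up; absent = all eight markers down) are a
reconstruction from the published marker list and prose and are
YAML-overridable; FOXP3 and CD79A are left out of the activated conjunction
by default because activation is defined by the cytotoxic-response genes,
with the all-marker variant available via configuration.

The CytAct call uses GZMB + PRF1 (the perforin gene; the frequently seen
"PFN1" is treated as an alias of PRF1, and the GZMA-based variant of the
original cytolytic-activity definition is not used). Expression strata are
symmetric by default (high: z ≥ +κ, low: z ≤ −κ, default κ = 1, boundaries
inclusive so ties are deterministic); the symmetric reading is chosen
because both the low and the high group are analyzed downstream.

## Mutation filtering and the enrichment screen

The inclusion filter counts mutation **records** (a patient may contribute
several records for one gene); the default threshold is ≥ 10 records.
Contingency tables, by contrast, always use **patient-level** mutation
status, which is the only design under which comparing "mutation
frequencies" across subtypes is well-defined. The omnibus test is the
Freeman–Halton 2×3 exact test computed by exhaustive enumeration of tables
with the observed margins in log-space (`gammaln`), two-sided by the
point-probability rule with the conventional `(1 + 1e-7)` relative
tolerance; pairwise subtype-vs-rest 2×2 Fisher tests (scipy, same two-sided
rule) are reported alongside. Significance is flagged on the **raw** omnibus
p < α (default 0.05) to match a raw-significance screening design, with
Benjamini–Hochberg q-values additionally reported so the screen's multiplicity
inflation stays visible. The screen can run overall and within HPV strata.
The non-synonymous vocabulary defaults to the nine standard cBioPortal-style
coding classes; unknown classes are dropped with a warning.

## Metabolic phenotyping

Upregulation frequency of a gene in a stratum is the fraction of samples
with z strictly > 0, consistent with the subtype boundary rule. Panel genes
missing from a matrix are dropped (reported, never imputed) since panCancer
matrices may lack symbols. Per-gene strata comparisons reuse the 2×2 Fisher
test; panel-level comparison is a **Welch** (unequal-variance) unpaired
two-tailed t-test over the per-gene fraction vectors — Welch as the robust
default, with the equal-variance Student variant a config switch away. The
relative phenotype
normalizes the two panel mean fractions to shares summing to 1. An export of
(gene, panel, weight = fraction) rows supports frequency-weighted word-cloud
rendering, which itself is out of scope. A mutated-vs-wildtype metabolic
comparison needs no separate code path: any binary sample partition can be
passed as strata.

## Survival

The Kaplan–Meier estimator is the standard product-limit form with Greenwood
variance; censored observations at t count as at risk through t. The
two-group test is Gehan's generalized Wilcoxon — the "Wilcoxon" pairing of
KM analyses in mainstream statistics packages — i.e. a weighted log-rank
with w_i = n_i, statistic `[Σ w_i (d_iA − e_iA)]² / Σ w_i² v_iA` referred to
χ²(1); setting w_i = 1 recovers the plain log-rank (config switch,
cross-checked against lifelines). The headline contrast is activated vs
pooled suppressed+absent; unclassified samples are excluded from both arms.

## Perturbation analysis

Because control and treated arms have unequal replicate counts, the pairing
unit for the treatment test is the **gene**: per gene, replicate means are
formed per condition and the paired two-sided t runs across the panel's
(treated − control) differences (identically the one-sample t of the
difference vector). Degenerate inputs are handled explicitly: an all-zero
difference vector gives t = 0, p = 1; a constant nonzero shift gives
t = ±∞, p = 0. Baseline characterization z-scores control replicate means
across cell lines per gene and compares each line's panel values against the
pooled other lines (Welch t) — pooled-others rather than a fixed reference
line, configurable by the caller through the table passed in. Extension gene
lists are merged onto the base panels with alias-aware deduplication; the
shipped extension lists are synthetic stand-ins (the original curated lists
are not public) constructed with 2 and 27 overlaps so the merged sizes of 52
and 116 arise from counting.

## Synthetic cohort generator

The generator emulates the statistical structure of the analyzed cohorts,
not RNA-seq physics. Expression is drawn directly on the z-scale
(background genes i.i.d. N(0,1) per sample) because every downstream rule
consumes z-scores. Defaults are the study conditions:

* n = 530 with subtype proportions 20/35/100/375 (activated / suppressed /
  absent / unclassified) and immune shift δ = 3 sd on the eight marker genes
  in each subtype's required directions;
* planted mutated gene (default EP300) at rate 0.5 in the activated subtype
  vs 0.05 elsewhere, plus 20 neutral genes at the base rate; record counts
  include occasional Poisson multi-hits so record and patient counts differ;
* regulator gene (EP300) ~ N(0,1) with glycolysis genes
  `ρ·reg + √(1−ρ²)·ε` and OXPHOS genes `−ρ·reg + √(1−ρ²)·ε`, ρ = 0.8;
* exponential survival with the activated hazard (5e-4/day) half that of
  the other subtypes (1e-3/day), censored by independent
  Uniform(0, 3/λ_max) — roughly 20–40 % censoring at these defaults;
* per-subtype HPV-positive rates (0.45 / 0.14 / 0.06 / 0.13) and
  site/stage distributions echoing the cohort's covariate gradients.

Unclassified samples are produced by **rejection sampling**: immune values
are redrawn until no subtype rule is satisfied. Two subtleties matter.
First, the violation is checked against each gene's *anticipated cohort
mean* (the mixture mean implied by the planted shifts), because cohort
re-standardization recentres every gene there — a violation relative to raw
zero would not survive z-scoring. Second, the guarantee is exact only at
the anticipated threshold: sampling noise in the empirical mean
(≈ sd/√n) flips samples lying within that margin of a rule boundary, so at
the default proportions roughly 10–15 % of truly-unclassified samples are
absorbed into a subtype, inflating the assigned activated group relative to
truth. Recovery of the *planted* labels is unaffected (≥ 90 % at δ = 3) and
a δ = 0 all-unclassified cohort classifies ≲ 1 % of samples. One integer
seed feeds a single `numpy.random.default_rng` stream; identical configs
are byte-identical.

The generator does **not** model count noise (negative binomial), tumor
purity, copy number, batch effects, or gene–gene correlation beyond the
planted programs — passing tests demonstrate correctness of the estimators
and rules under the planted model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 300–800 samples, 100 background
genes, 100-seed detection loops and 200/1000-seed null calibrations —
sizes at which every planted effect is comfortably detectable and a full
run finishes in well under half an hour on one CPU. Null calibrations of the
exact screen use equal subtype thirds (n = 300) and a 0.3 mutation rate:
exact conditional tests are conservative when expected cell counts are
small, so near-nominal rejection (0.05 ± 0.02) presumes a moderately
large-count regime. Survival-test calibration uses n = 100 per group with
~30 % uniform censoring. Floating-point contracts: z-score identities to
1e-9; exact-test agreement with rational-arithmetic enumeration oracles to
1e-12; closed-form t-statistics to 1e-9. Tie-breaks are deterministic
everywhere (alphabetical gene order on count ties; inclusive stratum
boundaries with the low rule applied last; stable sample order).

## Known limitations

* The shipped subtype panels are a documented reconstruction; analyses of
  real cohorts should confirm or override them via YAML.
* The enrichment screen's raw-p significance flag is intentionally
  anti-conservative across ~10³ genes; consumers should read the q-values.
* The Gehan-Wilcoxon p relies on the χ²(1) approximation, which degrades in
  very small groups (the estimator itself does not).
* Boundary absorption of unclassified samples (above) means assigned
  subtype counts exceed planted counts near rule boundaries; analyses that
  need clean groups should raise δ or the classification threshold.
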