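# scnadriver

Integration of somatic copy-number alterations (SCNA) with tumor expression
in paired tumor/normal cohorts: discovery of copy-number-driven genes,
gain/loss frequency landscapes, nearest-template subclass prediction, and
survival stratification.

## The problem

Recurrent arm-level deletions and amplifications are among the most common
somatic events in solid tumors. For any single gene inside such a region the
question is whether its expression actually follows its DNA copy number —
i.e. whether it is a *dosage-driven* gene, a plausible functional carrier of
the event — or merely a passenger. `scnadriver` implements the integrative
screen used to answer this in cohorts of paired tumor (PT) and non-tumor
(NT) samples with both RNA-seq (FPKM-like abundances) and segmented
SNP-array copy number (SEG files), such as a liver-cancer cohort where loss
of the 13q14 arm (carrying *MRPS31* and *RB1*) marks an aggressive,
short-survival subgroup.

## The method

For each gene *g* and tumor sample *s*, two log-ratios are formed:

- deregulated expression, `DE[g,s] = log2((FPKM_PT[g,s] + c) / (mean_NT FPKM[g] + c))`;
- copy-number alteration, `SCNA[g,s] = log2(DCN_PT[g,s] / mean_NT DCN[g])`,

where the gene-level copy number `DCN` comes from overlap-weighted mapping
of segment values onto gene intervals, and genes with copy-number data in
fewer than half the tumors are dropped. A gene is called **SCNA-dependent**
when three gates all pass:

1. `|mean DE| > 0.3` with a permutation Welch-*t* p-value `< 0.005`
   (NT vs PT, add-one permutation p);
2. the mean SCNA fold change has the same sign as the DE fold change;
3. Pearson *r*(DE, SCNA) `> 0.5` across the samples carrying both assays,
   with `p < 0.005`.

Around this core, the package provides:

- **landscape** — upper/lower-quartile stratification on one gene, per-gene
  gain/loss calls at `|log2 DCN| > 0.2`, signed frequency profiles in
  genomic order, and the differential landscape (`|Δfrequency| > 0.2`)
  between the strata;
- **ntp** — Nearest Template Prediction: cosine distance of each sample's
  z-scored expression to ±1 signature templates, significance by
  random-gene-set resampling, Benjamini–Hochberg FDR across samples, and
  Fisher's exact enrichment of calls between groups;
- **survival** — Kaplan–Meier curves, Cox–Mantel log-rank tests and
  univariate Cox regression (Breslow ties, Wald CIs; hazard ratios per SD
  of expression), including DCN-conditioned substratification;
- **simulate** — a synthetic-cohort generator that plants arm-level events,
  dosage-coupled genes, subclass signatures and expression-driven survival
  with known ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import scnadriver as sd
from scnadriver import preprocess, association, landscape, survival

cohort, truth = sd.simulate_cohort(seed=1)           # 376 tumors with DCN,
ann = cohort.annotation                              # 371 with expression
dcn_pt = preprocess.map_segments_to_genes(cohort.dcn_pt, ann)
dcn_nt = preprocess.map_segments_to_genes(cohort.dcn_nt, ann)
dcn_pt, removed = preprocess.filter_low_coverage_genes(dcn_pt)
de = preprocess.compute_de_matrix(cohort.expression_pt, cohort.expression_nt)
scna = preprocess.compute_scna_matrix(dcn_pt, dcn_nt)

records = association.associate(
    de, scna, np.log2(cohort.expression_pt + 1), np.log2(cohort.expression_nt + 1),
    B=9_999, rng=np.random.default_rng(0), samples=cohort.intersection_samples)
records = association.select_scna_dependent_genes(records)
hits = records[records.selected]

strat = landscape.stratify_quartiles(de.loc[truth.driver_gene])
km_lo, km_hi, lr = survival.stratified_survival(cohort.clinical, strat)
table = survival.hazard_table(cohort.clinical, de, [truth.driver_gene])
```

Output of the accompanying print statements:

```
93 SCNA-dependent genes (93 down with copy loss, 0 up with copy gain)
mean dosage correlation of hits: r = 0.69
quartile groups: n = 93 per arm
median OS low vs high: 15.7 vs 47.4 months
log-rank chi2 = 30.8, p = 2.92e-08
Cox HR per SD of g13_0200 expression: 0.61 (95% CI 0.53-0.70)
```

The screen recovers the planted 13q-like deletion-arm dosage genes (all
selected hits are downregulated with copy loss, mean dosage correlation at
the simulated value of 0.7); tumors in the lowest driver-expression quartile
live dramatically shorter (median 15.7 vs 47.4 months), and one SD more
driver expression carries a hazard ratio of 0.61 — low expression of the
driver is the adverse state, as designed.

The same pipeline is available from the shell:

```bash
scnadriver simulate  --seed 1 --out sim/
scnadriver preprocess --seg-pt sim/dcn_pt.seg --seg-nt sim/dcn_nt.seg \
    --expr-pt sim/expression_pt.tsv --expr-nt sim/expression_nt.tsv \
    --annotation sim/annotation.bed --out prep/
scnadriver associate --de prep/de.tsv --scna prep/scna.tsv \
    --expr-pt sim/expression_pt.tsv --expr-nt sim/expression_nt.tsv --out assoc/
scnadriver landscape --scna prep/scna.tsv --annotation sim/annotation.bed \
    --stratify-gene g13_0200 --out land/
scnadriver ntp      --expr sim/expression_pt.tsv --templates sim/templates.tsv \
    --linear-scale --out ntp/
scnadriver survival --clinical sim/clinical.tsv --de prep/de.tsv \
    --stratify-gene g13_0200 --hazard-genes g13_0200 --out surv/
```

Every subcommand writes TSV artifacts plus a `manifest.json` recording
inputs, parameters, seed and package version.

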