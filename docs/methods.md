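# Methods

This note documents the models, conventions and numerical choices behind
`scnadriver`, and what the synthetic cohort does and does not emulate.

## Coordinates and formats

All genomic intervals are held internally as 0-based half-open spans;
conversion happens only at I/O boundaries. SEG input is read as 1-based
inclusive by default (a row `start=1 end=1000` becomes `[0, 1000)`), with a
`dialect` switch because public segmented-copy-number exports are ambiguous
on this point. Chromosome labels are normalized (optional `chr` prefix
stripped) against the ordered set 1..22, X, Y, which defines genomic order
for every genome-wide output. Strand is ignored throughout: copy number and
abundance are strand-agnostic quantities. Validation is strict by default —
overlapping segments within one sample/chromosome are an error — with a
permissive mode that downgrades overlaps to warnings for messy real exports.

## Gene-level preprocessing

Segment values map to genes by overlap: a gene fully inside one segment
inherits its value; a gene spanning several segments gets the
overlap-length-weighted mean (equivalent to a per-base average over covered
bases, and tested against exactly that brute force); a gene with no covering
segment is missing for that sample. Weighted-mean handling of spanning genes
is a deliberate choice — single-segment containment is the unambiguous case,
and length weighting is the natural extension that keeps the per-base
interpretation.

Genes with copy-number data in strictly fewer than 50% of tumor samples are
excluded before association (the boundary is strict: exactly-half coverage
is retained). The DE matrix uses a pseudocount `c` (default 1.0 FPKM,
configurable) so that zero-abundance genes stay finite and an all-zero gene
maps to exactly 0; the NT reference is the mean over **all** normal
samples, not only paired ones — pairing matters only for cohort assembly of
the copy-number arm. Both DE and SCNA are log2-scale matrices, and every
downstream threshold (0.3 fold change, ±0.2 gain/loss call) is interpreted
on that scale.

## The association screen

Differential expression uses Welch's *t* (robust to the very unequal normal
vs tumor group sizes) with a permutation p-value. Monte Carlo p-values are
add-one, `p = (1 + #{|t*| >= |t|}) / (B + 1)`, so they are never zero; when
the number of label arrangements is at most `B` the test switches to
exhaustive enumeration and reports the exact fraction of arrangements at
least as extreme (the observed one included). Default `B = 9,999`, which
resolves the 0.005 and 1e-4 decision thresholds. Genome-wide screens share
one permutation plan across genes — the same label shuffles for every gene —
for reproducibility and speed (the per-gene null is unchanged; only the
joint dependence across genes is affected, which the selection rule never
uses). Zero pooled variance yields `t = 0, p = 1` by convention.

Dosage correlation is Pearson's *r* between DE and SCNA across the samples
holding both assays, with the two-sided p from the *t* transform at `n - 2`
degrees of freedom; genes with fewer than 3 complete pairs or zero variance
are reported missing. The selection gate uses **signed** `r > 0.5`, not
`|r|`: dosage dependence is positive by construction, and an anticorrelated
gene is not a dosage gene. No multiplicity correction enters the selection
rule itself — the thresholds are raw, as is conventional for this style of
screen — but BH-adjusted q-values are emitted as extra columns for readers
who want them.

## Stratification and landscapes

Quartile groups have size `k = round-half-to-even(N/4)`; this banker's
rounding is the unique rule consistent with groups of 94, 93 and 52 from
cohorts of 376, 371 and 210 samples. Ties are broken by ascending sample id
for determinism. The median split sends exact-median samples to the low
group (again for determinism; the choice is recorded in the run manifest),
so an odd-sized stratum splits one apart, e.g. 93 into 47 low / 46 high.

Gain/loss calls threshold log2 copy ratio strictly at ±0.2; a value exactly
at the threshold is neutral. Frequency profiles divide by the per-gene
count of non-missing calls in the group (the coverage filter caps
missingness below half, so denominators stay meaningful), with losses
reported as negative frequencies so the landscape plots below zero.
Differential landscapes difference gain and signed-loss frequencies
separately (low − high) and flag genes where either difference exceeds 0.2
in magnitude. The TSV profile is the tested artifact; the PNG is a
convenience rendering.

## Nearest-template prediction

Templates are pure ±1 direction vectors over signature genes. Expression is
gene-wise z-scored over the whole prediction cohort jointly (`ddof = 1`;
zero-variance genes dropped); linear-scale input is log2-transformed with a
pseudocount first. Each sample is assigned the class of minimum cosine
distance. The null distance distribution per sample comes from `R = 1,000`
random gene sets of the winning signature's size, drawn uniformly without
replacement from all measured genes, independently per sample; the add-one
resampling p is then BH-adjusted **across samples** (one test per sample)
and calls with FDR ≥ 0.05 are reported "unclassified". Signature genes
absent from the matrix are dropped per class with a warning; a class
retaining fewer than 5 genes is dropped entirely. Fisher's exact test
(two-sided, hypergeometric) measures per-class enrichment between sample
groups; the odds ratio is the sample cross-product ratio with a Haldane 0.5
correction when a cell is empty.

## Survival

Kaplan–Meier curves and the Cox–Mantel log-rank statistic are computed via
lifelines (events precede censorings at tied times, the standard
convention). The univariate Cox model is fit in-package: Breslow tie
handling, damped Newton iteration (step halving when the partial likelihood
does not improve), convergence at `|score| < 1e-8` or 50 iterations, Wald
95% CIs and p-values from the observed information — the forest-plot
convention. Breslow ties are adequate for the continuous event times the
simulator produces; on heavily tied data, hazard ratios will be attenuated
relative to Efron or exact methods. A coefficient diverging past |log HR| =
15 is treated as a monotone likelihood (perfect separation) and flagged
with an unbounded CI rather than a spurious Wald interval. Expression
covariates are standardized before fitting, so hazard ratios are per
standard deviation; DCN-conditioned substratification keeps samples whose
log2 copy ratio for the conditioning gene is at or above −0.2 ("wild type")
or strictly below it ("deleted").

## The synthetic cohort

The generator produces the statistical skeleton the analysis assumes, at
desk scale, with full ground truth. Defaults (the study conditions for all
recovery tests):

| parameter | default | meaning |
|---|---|---|
| cohort | 376 DCN tumors (all paired), 371 expression tumors, 369 shared, 50 expression normals | sample-count structure of a paired SNP-array/RNA-seq cohort |
| genome | 4 chromosomes × 500 genes (10 kb genes, 60 kb spacing) | toy genome, genomic order exercised |
| deletion arm | chromosome 13, 250 genes, carrier fraction π = 0.4, shift μ = −0.7 log2 | a recurrently deleted "13q-like" arm |
| gain arm | chromosome 8, 250 genes, π = 0.3, μ = +0.6 | a recurrent gain hotspot |
| σ_c | 0.1 log2 | per-segment copy noise (SNP-array segment scatter) |
| dosage genes | 100 genes inside the deletion arm, slope β = 1.7 | expression follows copy number |
| σ_e | 0.62 log2 | expression noise |
| baseline | per-gene log2 FPKM ~ N(5, 1.5) | well-expressed genes (FPKM ≈ 32 median) |
| survival | h0 = 0.02/month, γ = −0.5 per SD of driver expression, uniform censoring on (0, 120) months | low driver expression is adverse |
| templates | 2 classes × 50 signature genes, shift Δ = 1.5, 25% of tumors each | planted subclasses |

β and σ_e were chosen together so the theoretical dosage correlation
`ρ = β·sd(c) / sqrt(β²·var(c) + σ_e²)`, with
`var(c) = μ²π(1−π) + σ_c²`, equals 0.70 for deletion-arm dosage genes —
the regime where a dosage screen should succeed but is not trivial. The
closed form is exported (`theoretical_dosage_correlation`) and the
empirical correlation is tested against it at n = 1000 within ±0.05.

Copy-number noise is applied at **segment** level: each chromosome of each
sample is randomly partitioned into 3–6 segments with independent log2
values, and carried events shift whole regions after splitting segments at
event boundaries. This means downstream segment-to-gene mapping (including
spanning genes and weighted means) is genuinely exercised rather than
bypassed. A small segment-drop rate (1%) produces realistic missing
coverage. One master seed fans out into named substreams (baseline, copy
number, expression, survival, templates), so changing one component's
parameters never perturbs another component's draws, and the whole bundle
is byte-identical for a fixed seed.

What the generator does **not** emulate: tumor purity and ploidy shifts,
allele-specific copy number, GC/wave artifacts, batch effects, library-size
variation, gene-length effects on FPKM, correlated expression programs
beyond the planted signatures, and non-proportional hazards. Passing
recovery tests therefore demonstrate that the implementation is correct
under the stated generative model — not that the thresholds are optimal for
any particular real cohort.

## Problem sizes in the test suite

Unit tests run a reduced cohort (2 chromosomes × 80 genes, ~60 tumors);
calibration and recovery checks use the sizes their claims require: the
permutation type-I check at 2,000 null genes (30 vs 30, B = 999), the
selection-recovery and landscape checks on the full default cohort, the
subclass-prediction check at 40 samples per class with R = 1,000 resamples
plus three 60-sample pure-noise cohorts, Cox bias over 200 replicates of
n = 300, and log-rank null uniformity over 500 replicates of 200 vs 200.
The coverage-filter arithmetic is checked at full transcriptome scale
(58,387 genes). Fisher's exact p is verified against integer-arithmetic
enumeration for every 2×2 table with total count ≤ 40.

## Known limitations

- The permutation screen's shared plan makes per-gene p-values exchangeable
  but not independent across genes; q-value columns inherit this.
- Quartile stratification on a gene with missing values drops those samples
  first, so group sizes reflect the informative cohort (e.g. 93 rather than
  94 when a handful of samples lack copy number for the stratifying gene).
- The Cox implementation is univariate by design; no multivariate
  adjustment, time-dependent covariates or competing risks.
- NTP confidence is resampling-based and per-sample; it does not model
  correlation between signature genes, so strongly co-expressed non-template
  programs can inflate null distances on real data.
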