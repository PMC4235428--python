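# Methods

This note documents the statistical models, algorithms and design
choices behind `pedphewas`, in the order data flows through the
pipeline.

## The analysis model

A phenome-wide association study (PheWAS) inverts the usual GWAS logic:
a curated panel of variants is tested against every clinical phenotype
an EMR can support. Here each phenotype is a binary phecode indicator
and each test is a logistic regression

    logit P(y_i = 1) = b0 + b1 g_ij + c1 PC1_i + c2 PC2_i

with `g_ij` the additive dosage (0–2 copies) of the minor allele of
variant j, and the top two genotype principal components adjusting for
population stratification. `b1` is the per-allele log odds ratio; its
two-sided Wald test provides the association p-value.

## Phecode phenotyping

ICD-9 events are mapped to phecodes; a subject is a **case** for a
phecode when at least `min_code_count` (default 1) of their events map
to it. Controls are defined by exclusion: a non-case carrying any
phecode inside the phecode's exclusion range is **excluded** (neither
case nor control), everything else is a **control**. Subjects with no
mapped events at all are controls for every phenotype unless excluded.
The three statuses always partition the cohort. Phenotypes enter the
scan only with case count strictly greater than `min_cases`
(default 20).

Two related phenotypes can be pooled with `combine`: case if case of
either, excluded if excluded for either (and not a case), control only
if control for both. Exclusion ranges are intervals of phecode values
(the public map convention), not ICD-9 intervals.

The bundled map (`data/phecode_map_synthetic_mini.csv`) is a synthetic
~40-phecode miniature spanning all 14 concept-path categories; the full
published map is an external resource and any map in the documented CSV
schema (`icd9,phecode,description,exclude_lo,exclude_hi,category`) can
be supplied instead.

## Quality control

Defaults follow the standard array-QC recipe: variants are removed for
missingness > 5%, exact-test Hardy–Weinberg disequilibrium p < 1e-3 in
controls, or MAF < 1%; samples for call rate < 98%; and variants whose
allele frequencies differ between the two recruitment sites at
p < 1e-5 (2x2 allele-count chi-square, Fisher when an expected cell is
below 5) are treated as genotyping artifacts and dropped. The HWE test
is the exact conditional test (probabilities of heterozygote counts
given the minor-allele count; two-sided p sums configurations no more
likely than the observed one) — at a 1e-3 threshold the exact test is
the field standard and no mid-p correction is applied. Which subjects
count as "controls" for HWE is configurable: the pipeline default uses
subjects who are cases for no eligible phenotype, falling back to the
whole cohort when that set is empty.

Dosage data are hard-called at a 0.1 tolerance for the HWE and site
tests (HWE is undefined on fractional dosages); association tests use
the dosages directly.

## Stratification adjustment

PCA uses the EIGENSTRAT standardization: each variant column is
centered at 2p̂ and scaled by sqrt(2p̂(1−p̂)), missing entries
mean-imputed, monomorphic variants excluded. Scores are the top-K left
singular directions; eigenvalues are singular values squared over n so
the full spectrum sums to the total variance. Outliers are removed
iteratively (any subject beyond 6 SD on a retained axis, PCA recomputed,
up to 5 rounds — the EIGENSTRAT defaults, since the selection rule
behind the study's removed samples is not published). Genomic inflation
is λ = median(χ²₁)/0.45494 and is logged per phenotype when the case
count reaches 100.

## Multiplicity

Two r² estimators are used deliberately. LD *reporting* (`ld_stats`)
estimates two-locus haplotype frequencies by EM from unphased genotypes
(tolerance 1e-10, ≤1000 iterations) and derives D, D′ and r². LD
*pruning* (`prune`) uses the squared Pearson correlation of dosage
vectors (the PLINK `--indep-pairwise` convention) in a greedy
position-order sweep: a variant is dropped when r² > 0.5 with any kept
variant within 500 kb. The surviving quasi-independent variants define
the grid over which Benjamini–Hochberg q-values are computed, pooled
across phenotypes to mirror a single study-wide q column (a
per-phenotype option exists). Tests at pruned-away variants inherit no
q-value.

Adaptive permutation shuffles case/control labels (covariates stay
attached to subjects), refits, and counts permuted |Wald z| at or above
the observed one; sampling stops at 10 exceedances or 1,000,000 trials,
with p = (r+1)/(n+1). When the number of distinct labelings is within
the trial budget the null is enumerated exhaustively instead and
flagged.

## Conditional, interaction and power analyses

Conditional analysis appends the conditioning phenotype or genotype to
the covariates (covariate augmentation, not stratification); a
conditioning vector with r² > 0.99 to the tested genotype is rejected
as collinear. Interaction tests add the product term g1·g2 and report
its Wald p.

The power engine is the normal approximation to the allelic
two-proportion test: with control risk-allele frequency p0 and
per-allele OR, p1 = OR·odds0/(1+OR·odds0) and

    power = Φ(|p1−p0| / SE_alt − z_{1−α/2}),
    SE_alt² = p1(1−p1)/(2·n_cases) + p0(1−p0)/(2·n_controls).

`min_cases` bisects this monotone function. A binomial simulation
oracle (`simulated_power`) draws allele counts at the design frequencies
and applies the same two-proportion z-test; the package treats published
"cases needed" figures as upper bounds on the analytic minimum, because
QUANTO-style calculators make unpublished model assumptions. Notably,
the often-quoted rule that ~200 cases give 80% power at RAF 10% and
OR 1.5 is *not* reproducible under the allelic approximation (it yields
roughly 0.6–0.7 power); the allelic closed form is retained because it
is fully specified and simulation-checkable.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with a truth table for recovery tests:

* **Population structure** — Balding–Nichols: subpopulation allele
  frequencies p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral
  frequency at divergence F (FST), genotypes Hardy–Weinberg within
  subpopulation. Defaults: two subpopulations at F = 0.01 (mild
  within-European structure), a 4,268-subject cohort recruited at two
  sites in an 83/17 split.
* **LD blocks** — haplotype copy-with-mutation chains: each haplotype
  copies the previous variant's allele with probability `copy_prob`
  (default 0.9, r² ≈ copy_prob² at equal frequencies) or redraws from
  the subpopulation frequency. Chosen over multivariate-normal
  thresholding for tunability and exact HWE marginals.
* **Site artifacts** — designated variants get their frequency shifted
  by ≥ 0.15 (default 0.30) at the second site.
* **Phenotypes** — a logistic liability: subject i is a case for
  phecode k with probability
  logistic(α_k + Σ_j β_jk g_ij + loading_k·z_i), z_i the subpopulation
  indicator. α_k is calibrated by root-finding so the realized marginal
  prevalence matches the spec. Because the liability is logistic, the
  planted β are exactly the estimand of the analysis model, making
  recovery tests unbiased in expectation.
* **Events** — cases emit 1–3 ICD-9 codes with replacement from the
  phecode's code list; a configurable fraction of non-cases emit a code
  from the exclusion range so control exclusion is exercised; dates are
  uniform over a five-year window for schema realism only.
* **Reproducibility** — one RNG stream per stage (labels, frequencies,
  genotypes, missingness, events), split deterministically from the
  master seed; identical spec and seed give byte-identical output.

What the generator does **not** emulate: longitudinal visit dynamics,
code-count intensity differences between sick and healthy patients,
relatedness/pedigree structure, X-chromosome dosage, and realistic
genome-wide LD beyond block-local correlation. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every property of real EMR data.

## Numerical choices

* Logistic fits: IRLS from zero start; converged when max |score|
  < 1e-8 or relative log-likelihood change < 1e-10, ≤ 25 iterations.
  Non-convergence or |β| > 10 flags quasi-separation
  (`converged=False`); fits are flagged, never silently dropped, and no
  Firth correction is applied (a plain-logistic design choice; Firth is
  future work). Exact collinearity raises instead.
* CI multiplier fixed at 1.96 to match printed intervals.
* Missing genotypes: complete-case per test, mean-imputation only
  inside PCA and the liability model.
* Genomic coordinates 1-based; the regional report window is ±100 kb.
* TSVs use a fixed column order, `NA` for missing, and 3-significant-
  digit scientific notation for p/q columns.

## Problem sizes used by the test and acceptance suites

Simulation checks run at sizes chosen to make their Monte-Carlo error
small relative to the tolerance being asserted: type-I error on 5,000
null tests (n = 2,000, 100 variants × 50 phenotypes); FDR control over
50 replicate scans of 2,000 tests at n = 4,000 with 10% planted effects
(OR 1.8); CI coverage over 1,000 replicates at n = 5,000; inflation
adjustment on a structured cohort of 2,000 subjects with 2,000
scan tests; power designs confirmed with 1,000-replicate binomial
oracles.

## Known limitations

* The Wald test misbehaves under quasi-separation (Hauck–Donner); such
  fits are flagged, and the adaptive permutation path provides an
  empirical alternative for small case counts.
* BH q-values computed on the pruned grid leave pruned-away tests
  without a q; consumers wanting a complete column should re-run with
  pruning disabled (r² threshold 1.0).
* The allelic power approximation ignores covariates and
  genotype-level (rather than allele-level) sampling; its simulation
  oracle quantifies, but does not remove, that approximation.
* The EM haplotype frequencies equal phased counts only when phase is
  unambiguous; otherwise they are the unphased MLE, which can differ
  from phased tallies by O(n^-1/2).
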