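# Methods

## Model and procedure

The package implements an individual-level TWAS followed by cross-trait
pleiotropy mapping.

**Expression imputation.** GReX is the plain weighted sum of harmonized
effect-allele dosages, with no intercept and no normalisation: the
downstream regression is scale-equivariant, so rescaling GReX changes β
and its SE by reciprocal factors and leaves t and p untouched. Model
entries whose variant is absent from the panel are dropped (not imputed);
entries whose allele pair cannot be reconciled with the panel's ref/alt
(neither identity nor swap) are dropped with a warning. Strand-ambiguous
(A/T, C/G) entries are *kept* — with real data from mixed platforms this
risks silent flips, and callers merging external weight tables should
pre-filter if strands are uncertain.

**Missing genotypes.** Imputation requires a complete panel. Missing cells
are filled per variant with the modal hard genotype: observed dosages are
rounded half-up (⌊d + 0.5⌋) to {0,1,2} only to determine the mode, ties
break to the lower genotype, and observed cells are never altered. A
variant with no observed value is an error rather than a guess.

**Association.** Status (0/1) is the outcome and GReX the predictor, with
intercept, sex, age, PC1, PC2 as covariates — the convention of
individual-level TWAS. The wording "regression of predicted expression
with status" is ambiguous about roles; for the simple model without
covariates the two-sided p is identical either way, with covariates it is
not, and the outcome-status direction is the one kept. The fit is OLS on
the binary outcome (a linear probability model); a logistic alternative
exists behind `family="logistic"` but is off by default. Computationally,
status and all GReX columns are residualised on the shared covariate
design via a QR decomposition (Frisch–Waugh), making each gene's fit a
dot product; tests assert equality with full statsmodels OLS to 1e-10.
Zero-variance (degenerate) GReX columns are excluded *before* FDR so they
do not inflate the test count, as are genes intersecting the MHC interval
(chr6:28,477,797–33,448,354, hg19; complex LD). BH is applied once across
all gene–tissue tests jointly; significance is Q < 0.001 strictly.

**Locus classification and model-variant annotation.** A significant gene
is *known* when its span intersects any target-trait lead ± 1 Mb on the
same chromosome, else *novel* (the window anchors on the lead variant's
position). Per model, variants with target-GWAS p ≤ 5×10⁻⁸ (inclusive
boundary) and p < 1×10⁻⁴ are counted; variants absent from the summary
count only toward the model size. The strongest-effect tissue maximises
|β| over all of a gene's records, with ties broken by smaller p, then
lexicographic tissue name.

**R² loci and pleiotropy.** A lead's locus spans the min/max positions of
panel variants with r² > 0.5 (strict) to the lead, searched within 2 Mb of
the lead; r² is the squared Pearson correlation of genotype-dosage vectors
(phased-haplotype correlation would differ slightly; dosage correlation is
what an unphased reference panel supports), defined as 0 for constant
vectors. The search window is a practical bound: under the block LD model
long-range r² > 0.5 cannot occur, and in real data 2 Mb comfortably
contains a GWAS signal's LD mass. A lead absent from the panel is an
error at the single-locus API and a logged single-position locus in batch
construction. Merging is transitive and cross-trait *before* category
assignment; coordinates are 1-based inclusive everywhere (touching
intervals share a bp and merge), and only BED I/O converts to 0-based
half-open. Both locus flavours (raw R² and 1-Mb-extended-then-merged) are
produced, as the two give very different gene-overlap rates. Category
enrichment uses the two-sided Fisher convention that sums all
hypergeometric point probabilities ≤ the observed table's (the R
`fisher.test` convention); degenerate margins give p = 1. The tissue-count
comparison uses the two-sided Mann–Whitney U, exact by enumeration when
combined n ≤ 25 without ties, otherwise the normal approximation with tie
and continuity correction.

**Gene-set overrepresentation.** One-sided hypergeometric upper tail
against a background defaulting to the predictable-gene universe, BH
adjustment sharing the association stage's implementation, and a combined
score ln(p)·z where z measures the deviation of the term's p-value rank
from its rank under random queries. The rank null is estimated by 100
random query lists (sampled without replacement, equal size) — the
quantity is named in the literature without a prescribed estimator, so
the estimator here is defined explicitly and seeded.

## Synthetic cohorts: what they emulate and what they do not

`synthio` generates the study conditions end to end. Variants sit at
regular 10 kb spacing on 4 chromosomes; within blocks of 5 variants, two
latent Gaussian haplotypes per sample with equicorrelation are thresholded
at each variant's MAF quantile (MAF ~ U(0.05, 0.5)) and summed to
dosages. Thresholding attenuates correlation, so the configured
`within_block_correlation` is the *target allele correlation*, mapped to
the latent scale by the tetrachoric relation sin(πρ/2) (exact at MAF 0.5);
with the default ρ = 0.8, same-block pairs of similar MAF land around
r² ≈ 0.5–0.7 and cross-block pairs are independent. Genes (20 kb spans)
are laid out uniformly; each gene–tissue model draws 2–6 variants
uniformly from the gene span ± 1 Mb with N(0,1)/√K weights, and 20% of
entries name the reference allele as effect allele so harmonization is
always exercised. Liability is Σ α·GReX over causal genes (first tissue's
models) + 0.1·sex + 0.01·age + 0.1·PC1 + 0.1·PC2 + N(0,1), thresholded at
the empirical (1 − K) quantile so realized prevalence is exact at any n —
a fixed Gaussian threshold would make small-cohort prevalence noisy for
no benefit. Defaults are a desk-scale stand-in for the real design
(tens of thousands of samples, 27 tissues): 2,000 samples, 150 genes, 3
tissues, 10 causal genes with alternating effects ±0.5, prevalence 0.5
(case/control ascertainment, not population prevalence). GWAS catalogs
give each trait leads with p ~ 10^-U(8.5,20), graded sub-threshold
p-values (10^-U(4.5,7)) for the lead's block mates, U(0,1) elsewhere; the
first `anchored_traits` traits place one lead at the panel variant nearest
each causal gene's midpoint and raise the causal genes' model variants to
genome-wide significance, emulating the dense signal at a true disease
locus and giving constructed pleiotropy for recovery tests.

Deliberately missing from the emulation: realistic human LD maps and
long-range structure, ascertainment and participation bias, imputation
uncertainty in dosages, population stratification actually expressed in
the genotypes (PCs are synthetic N(0,1) covariates), and trained — rather
than drawn — prediction weights. Passing tests therefore demonstrate the
*statistical machinery* (calibration, power, interval algebra, exact
tests) under the assumed generative model, not performance on real
cohorts. One realistic artefact is present and worth knowing: with a 1 Mb
cis window on a dense synthetic genome, neighbouring genes share weighted
variants, so non-causal neighbours of causal genes can reach significance
— the co-regulation effect that makes real TWAS report several genes per
locus, and the reason causal-recovery rates are evaluated per causal gene
rather than per significant gene.

## Numerical choices

- Degenerate GReX: variance ≤ 1e-14 (raw) or residual sum of squares
  ≤ 1e-12 after covariate projection.
- p-values are clipped into (0, 1] at the smallest positive double before
  BH, which requires p ∈ (0, 1].
- Percentages in reports are rounded half-up (decimal arithmetic, not
  banker's rounding) to 2 decimals, 1 where conventionally printed so.
- Dosage VCF writing uses 6 significant digits; FORMAT floats are parsed
  as float32 by htslib, so round-trips are exact to ~1e-6, while all TSV
  round-trips are exact.
- Every generator draws from `default_rng([seed, stage_id])`, so stages
  are independently reproducible from one config seed.

## Problem sizes used in validation

The null-calibration run uses 20 cohorts of 2,000 samples with 300 genes
× 3 tissues (900 joint tests each); the recovery run uses 2 cohorts of
4,000 samples with 10 causal genes each; interval algebra is checked on
1,000 random instances against a per-bp union oracle, and the exact tests
against full enumeration at small totals. These sizes give stable
stochastic checks while keeping the full suite fast on a single CPU.

## Known limitations

- Linear-probability OLS on a binary outcome is the analysis convention,
  not the best estimator near prevalence extremes; use the logistic flag
  for K far from 0.5.
- The Fisher two-sided convention differs from doubling the smaller tail;
  alternate conventions give slightly different p on asymmetric tables.
- LD r² from genotype dosages differs slightly from haplotype r²; loci
  built from small reference panels are noisy near the 0.5 threshold.
- The rank-deviation z depends on the random-query null size (default
  100); very small libraries give coarse z values (a single term is
  pinned to z = 0).
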