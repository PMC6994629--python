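# twaspleio

Individual-level transcriptome-wide association analysis (TWAS) with
cross-trait pleiotropy mapping, for genotyped case/control cohorts — and a
synthetic-data module that generates cohorts with the same statistical
structure so the whole pipeline can be exercised and validated at desk
scale.

## The analysis

A TWAS asks whether the *genetically regulated* component of a gene's
expression differs between cases and controls. For each gene *g* and
tissue *t*, a pre-trained sparse cis-eQTL model supplies weights
*w<sub>k</sub>* on effect alleles, and the genetically regulated expression
(GReX) of sample *i* is the weighted dosage sum

    GReX_ig = Σ_k  w_k · d_ik

with dosages harmonized to the model's effect allele (d → 2 − d when
effect and non-effect alleles are swapped relative to the panel). Each
gene–tissue pair is then tested by ordinary least squares of case/control
status on GReX, adjusting for sex, age and two genotype principal
components:

    status_i = β0 + β · GReX_ig + γ1·sex + γ2·age + γ3·PC1 + γ4·PC2 + ε

β > 0 means predicted expression is higher in cases. P-values of **all**
gene–tissue tests are adjusted jointly by Benjamini–Hochberg; pairs with
Q < 0.001 are called significant. Genes in the MHC region
(chr6:28,477,797–33,448,354, hg19) are excluded before adjustment, and
each significant gene is classified *known* or *novel* by whether its span
lies within ±1 Mb of a target-trait GWAS lead variant.

The pleiotropy stage intersects the resulting gene list with **R² loci**
of other complex traits: for every trait's genome-wide-significant lead
(p ≤ 5×10⁻⁸), the locus is the interval spanned by all reference-panel
variants with r² > 0.5 to the lead; overlapping loci are merged across
traits (optionally after a ±1 Mb extension), genes are assigned to the
categories of the loci they intersect, and category enrichment of the
target gene list against the full predictable-gene universe is tested by a
two-sided Fisher exact test. Gene-set overrepresentation (GMT libraries)
uses the one-sided hypergeometric tail with a rank-deviation combined
score ln(p)·z.

Because the real inputs of such a study (controlled-access genotypes,
PredictDB weight databases) cannot ship with a library, `twaspleio.synthio`
simulates them: LD-blocked dosages from thresholded latent Gaussian
haplotypes, sparse cis weight models with known causal genes, a
liability-threshold binary phenotype, and multi-trait GWAS catalogs whose
leads can be anchored inside causal genes to construct pleiotropy.

## Worked example

`examples/02_impute_and_associate.py` simulates 2,000 samples, 40 genes ×
2 tissues with 4 causal genes (|α| = 0.6), imputes GReX and runs the
association stage:

```
80 gene-tissue tests, 9 significant at q < 0.001
    gene    tissue      beta       se            p            q
GENE0037 tissue_00 -0.200690 0.015828 1.726586e-35 1.381269e-33
GENE0024 tissue_00  0.219115 0.017797 1.255658e-33 5.022632e-32
GENE0004 tissue_00 -0.122165 0.015272 2.103754e-15 5.610011e-14
...
true causal genes: ['GENE0003', 'GENE0004', 'GENE0024', 'GENE0037']
```

All four causal genes are recovered with the correct effect direction
(β < 0 for genes whose expression lowers liability). A few non-causal
neighbours also reach significance: their cis windows share weighted
variants with causal genes — the same co-regulation effect that makes
real TWAS report several genes per locus. The other examples cover cohort
simulation, R²-locus construction with category enrichment, gene-set
overrepresentation, and the one-command pipeline
(`twaspleio run --out DIR --seed 7`), whose `report.json` collects the
bookkeeping (tests run, significant pairs, unique genes, known/novel
split, locus-overlap percentages, Mann-Whitney tissue-count comparison).

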