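"""Synthetic cohorts with the statistical structure the analysis assumes.

The real study design — tens of thousands of genotyped cases and controls,
PredictDB-style per-tissue cis-eQTL weight models, and a catalog of GWAS
lead variants for dozens of other complex traits — rests on controlled-
access data.  This module generates desk-scale stand-ins with the same
structure so every downstream stage (expression imputation, association,
FDR, LD-locus pleiotropy, enrichment) can be exercised and validated:

* genotype dosages with block-structured linkage disequilibrium, built by
  thresholding equicorrelated latent Gaussian haplotypes at the minor
  allele frequency;
* sparse cis weight models per gene and tissue, with a known subset of
  causal genes;
* a binary phenotype from a liability-threshold model in which liability
  is the sum of the causal genes' genetic expression component, linear
  covariate terms and unit Gaussian noise, thresholded at the empirical
  (1 - prevalence) quantile so realized prevalence is exact;
* per-trait GWAS summary catalogs whose lead variants can be anchored
  inside the causal genes' cis regions (constructed pleiotropy) or placed
  at random (null).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import (
    DosagePanel,
    GwasSummary,
    VariantKey,
    WeightEntry,
    WeightModel,
)
from .pleio import TraitCatalog

logger = logging.getLogger(__name__)

# Trait groupings used when the caller supplies no category map; mirrors the
# kind of manual assembly of traits into disease groups the analysis expects.
DEFAULT_CATEGORIES = [
    "AMD",
    "neurological diseases",
    "autoimmune diseases",
    "metabolic traits",
    "cancer",
    "cardiovascular diseases",
    "organ function",
    "blood cells",
    "anthropometric traits",
    "complex eye diseases and traits",
    "immune-related traits",
    "lifestyle",
    "aging",
]

# Stage offsets mixed into the seed so each generator draws an independent,
# reproducible stream from the same config.
_STAGE = {"genotypes": 1, "annotation": 2, "weights": 3, "cohort": 4, "gwas": 5}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    n_samples: int = 2000
    n_variants: int = 1200
    n_genes: int = 150
    n_tissues: int = 3
    n_chromosomes: int = 4
    variant_spacing: int = 10_000  # bp between adjacent variants
    gene_length: int = 20_000  # bp span of each simulated gene
    ld_block_size: int = 5  # variants per LD block
    within_block_correlation: float = 0.8  # latent-Gaussian rho in [0, 1)
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_window: int = 1_000_000  # bp around the gene span for model variants
    weights_per_gene_range: tuple[int, int] = (2, 6)
    flip_effect_allele_prob: float = 0.2  # fraction of entries with effect = ref
    n_causal_genes: int = 10
    causal_effect_size: float = 0.5  # liability units per unit GReX
    prevalence: float = 0.5
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.1, "age": 0.01, "pc1": 0.1, "pc2": 0.1}
    )
    missing_rate: float = 0.0  # fraction of dosage cells set missing
    n_traits: int = 8
    leads_per_trait: int = 3
    shared_lead_fraction: float = 0.3  # leads drawn from a cross-trait shared pool
    anchored_traits: int = 1  # first k traits get leads inside causal genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within_block_correlation must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be contained in (0, 0.5]")
        for name in ("n_samples", "n_variants", "n_genes", "n_tissues", "n_traits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf_range", "weights_per_gene_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TruthSet:
    """Ground truth of a simulated study, for evaluation only."""

    causal_alpha: dict[str, float]  # gene id -> signed liability effect
    causal_tissue: str  # tissue whose model drives liability
    trait_leads: dict[str, list[str]] = field(default_factory=dict)
    trait_categories: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> DosagePanel:
    """Diploid dosages with block-constant LD from latent Gaussian haplotypes.

    Variants sit at regular spacing on ``n_chromosomes`` chromosomes.  Within
    each block of ``ld_block_size`` variants two latent haplotypes per sample
    are drawn from an equicorrelated Gaussian (pairwise correlation rho) and
    thresholded at the normal quantile of the variant's MAF; the two allele
    indicators sum to the dosage.  Blocks are independent.
    """
    rng = config._rng("genotypes")
    n, m = config.n_samples, config.n_variants
    per_chrom = int(math.ceil(m / config.n_chromosomes)) if m else 0
    variants: list[VariantKey] = []
    for j in range(m):
        chrom = f"chr{j // per_chrom + 1}" if per_chrom else "chr1"
        pos = (j % per_chrom) * config.variant_spacing + config.variant_spacing
        variants.append(VariantKey(chrom, pos, f"var{j:05d}", "A", "G"))

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = np.empty((n, m), dtype=float)
    # within_block_correlation is the target allele correlation; thresholding
    # attenuates latent Gaussian correlation, so invert the tetrachoric
    # relation (exact at MAF 0.5) to recover it on the latent scale
    rho = math.sin(math.pi * config.within_block_correlation / 2.0)
    start = 0
    while start < m:
        # blocks never span a chromosome boundary
        chrom_end = (start // per_chrom + 1) * per_chrom if per_chrom else m
        stop = min(start + config.ld_block_size, chrom_end, m)
        width = stop - start
        thr = stats.norm.ppf(mafs[start:stop])
        block = np.zeros((n, width), dtype=float)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indiv = rng.standard_normal((n, width))
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indiv
            block += (z < thr)
        dosages[:, start:stop] = block
        start = stop

    if config.missing_rate > 0 and n and m:
        mask = rng.random((n, m)) < config.missing_rate
        # keep at least one observed cell per variant so modal fill is defined
        full = mask.all(axis=0)
        mask[0, full] = False
        dosages[mask] = np.nan

    samples = [f"S{i:05d}" for i in range(n)]
    return DosagePanel(variants=variants, samples=samples, dosages=dosages)


def simulate_gene_annotation(config: SimulationConfig, panel: DosagePanel) -> pd.DataFrame:
    """Place genes at regular spacing on the panel's chromosomes."""
    chroms = sorted({v.chrom for v in panel.variants}, key=lambda c: int(c[3:]))
    spans: dict[str, int] = {}
    for c in chroms:
        spans[c] = max(v.pos for v in panel.variants if v.chrom == c)
    rows = []
    if chroms:
        per_chrom = int(math.ceil(config.n_genes / len(chroms)))
        g = 0
        for c in chroms:
            k = min(per_chrom, config.n_genes - g)
            if k <= 0:
                break
            step = max((spans[c] - config.gene_length) // max(k, 1), 1)
            for i in range(k):
                start = 1 + i * step
                rows.append((f"GENE{g:04d}", c, start, start + config.gene_length - 1))
                g += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Weight models
# ---------------------------------------------------------------------------

def simulate_weight_models(
    config: SimulationConfig,
    panel: DosagePanel,
    annotation: pd.DataFrame,
) -> tuple[list[WeightModel], TruthSet]:
    """Sparse cis models per gene and tissue, plus the causal-gene truth.

    Each model draws K variants uniformly from the gene's cis window (gene
    span extended by ``cis_window`` on both sides) with weights from a
    standard normal scaled by 1/sqrt(K), so the genetic expression component
    has comparable variance regardless of model sparsity.  A fraction of
    entries name the panel reference allele as effect allele, exercising
    allele harmonization downstream.  Causal genes receive alternating
    signed liability effects +/- ``causal_effect_size``; liability is driven
    by the first tissue's models.
    """
    rng = config._rng("weights")
    tissues = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, v in enumerate(panel.variants):
        by_chrom.setdefault(v.chrom, []).append((v.pos, j))

    models: list[WeightModel] = []
    lo, hi = config.weights_per_gene_range
    for row in annotation.itertuples():
        lo_pos = row.start - config.cis_window
        hi_pos = row.end + config.cis_window
        cis = [j for pos, j in by_chrom.get(row.chrom, []) if lo_pos <= pos <= hi_pos]
        if not cis:
            logger.warning("gene %s: empty cis window, no model simulated", row.gene)
            continue
        for tissue in tissues:
            k = min(int(rng.integers(lo, hi + 1)), len(cis))
            chosen = sorted(rng.choice(cis, size=k, replace=False).tolist())
            weights = rng.standard_normal(k) / math.sqrt(k)
            entries = []
            for j, w in zip(chosen, weights):
                v = panel.variants[j]
                if rng.random() < config.flip_effect_allele_prob:
                    entries.append(WeightEntry(v.id, v.ref_allele, v.alt_allele, float(w)))
                else:
                    entries.append(WeightEntry(v.id, v.alt_allele, v.ref_allele, float(w)))
            models.append(WeightModel(tissue=tissue, gene=row.gene, entries=entries))

    modeled_genes = sorted({m.gene for m in models})
    n_causal = min(config.n_causal_genes, len(modeled_genes))
    causal = rng.choice(modeled_genes, size=n_causal, replace=False).tolist()
    alpha = {
        g: config.causal_effect_size * (1 if i % 2 == 0 else -1)
        for i, g in enumerate(sorted(causal))
    }
    truth = TruthSet(causal_alpha=alpha, causal_tissue=tissues[0] if tissues else "")
    return models, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
    panel: DosagePanel,
    models: Sequence[WeightModel],
    truth: TruthSet,
) -> pd.DataFrame:
    """Liability-threshold case/control cohort with covariates.

    Liability is sum(alpha_g * GReX_g) over causal genes (imputed from the
    causal tissue's models on the missing-filled panel) plus linear covariate
    terms plus N(0, 1) noise.  Status is 1 for the ceil(prevalence * n)
    samples with the highest liability, so realized prevalence is exact.
    """
    from .grex import fill_missing_dosages, impute_expression

    rng = config._rng("cohort")
    n = panel.n_samples
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(50, 95, size=n)
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)

    liability = rng.standard_normal(n)
    ce = config.covariate_effects
    liability += ce.get("sex", 0.0) * sex + ce.get("age", 0.0) * age
    liability += ce.get("pc1", 0.0) * pc1 + ce.get("pc2", 0.0) * pc2

    if truth.causal_alpha:
        causal_models = [
            m
            for m in models
            if m.tissue == truth.causal_tissue and m.gene in truth.causal_alpha
        ]
        filled = fill_missing_dosages(panel) if np.isnan(panel.dosages).any() else panel
        expr = impute_expression(filled, causal_models, truth.causal_tissue)
        for g, a in truth.causal_alpha.items():
            if g in expr.genes:
                liability += a * expr.values[:, expr.genes.index(g)]

    n_cases = math.ceil(config.prevalence * n)
    status = np.zeros(n, dtype=int)
    if n_cases:
        order = np.argsort(-liability, kind="stable")
        status[order[:n_cases]] = 1

    return pd.DataFrame(
        {
            "sample_id": panel.samples,
            "status": status,
            "sex": sex.astype(int),
            "age": age,
            "pc1": pc1,
            "pc2": pc2,
        }
    )


# ---------------------------------------------------------------------------
# GWAS catalogs
# ---------------------------------------------------------------------------

def simulate_gwas_catalogs(
    config: SimulationConfig,
    panel: DosagePanel,
    truth: TruthSet,
    models: Sequence[WeightModel] | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[list[GwasSummary], list[TraitCatalog]]:
    """Per-trait GWAS summary statistics with genome-wide-significant leads.

    The first ``anchored_traits`` traits take one lead per causal gene,
    placed at the panel variant nearest the gene's midpoint (inside the gene
    when variant spacing permits), so their LD loci overlap the causal genes
    by construction; remaining traits mix leads from a shared cross-trait
    pool (pleiotropy) with private random leads.  Lead p-values are drawn
    below 5e-8, variants in the lead's LD block get graded sub-threshold
    p-values, and everything else is Uniform(0, 1).  In anchored catalogs
    the causal genes' causal-tissue model variants are additionally raised
    to genome-wide significance, emulating the dense association signal at
    a true disease locus.  Trait 0 is the target-disease ("AMD"-like)
    catalog; categories are assigned round-robin from a default 13-group
    list.
    """
    rng = config._rng("gwas")
    m = panel.n_variants
    vindex = panel.variant_index()

    anchor_ids: list[str] = []
    model_variant_cols: list[int] = []
    if truth.causal_alpha:
        gene_span = (
            {r.gene: (r.chrom, r.start, r.end) for r in annotation.itertuples()}
            if annotation is not None
            else {}
        )
        for g in sorted(truth.causal_alpha):
            gm = [mm for mm in (models or []) if mm.gene == g and mm.tissue == truth.causal_tissue]
            if gm:
                model_variant_cols.extend(
                    vindex[e.variant_id] for e in gm[0].entries if e.variant_id in vindex
                )
            if g in gene_span:
                chrom, start, end = gene_span[g]
                mid = (start + end) // 2
                near = [
                    (abs(v.pos - mid), v.id)
                    for v in panel.variants
                    if v.chrom == chrom
                ]
                if near:
                    anchor_ids.append(min(near)[1])
            elif gm:
                best = max(gm[0].entries, key=lambda e: abs(e.weight))
                anchor_ids.append(best.variant_id)

    n_shared = max(1, int(round(config.shared_lead_fraction * config.leads_per_trait)))
    shared_pool = (
        rng.choice(m, size=min(n_shared, m), replace=False).tolist() if m else []
    )

    traits = ["AMD"] + [f"trait_{t:02d}" for t in range(1, config.n_traits)]
    categories = {
        t: ("AMD" if i == 0 else DEFAULT_CATEGORIES[1 + (i - 1) % (len(DEFAULT_CATEGORIES) - 1)])
        for i, t in enumerate(traits)
    }

    summaries: list[GwasSummary] = []
    catalogs: list[TraitCatalog] = []
    block = config.ld_block_size
    for i, trait in enumerate(traits):
        lead_cols: list[int] = []
        if i < config.anchored_traits and anchor_ids:
            # anchored traits carry one lead per causal gene, like the target
            # trait's known loci covering its associated genes
            lead_cols = [vindex[a] for a in anchor_ids if a in vindex]
        elif m:
            for j in shared_pool:
                if len(lead_cols) >= config.leads_per_trait:
                    break
                if i >= config.anchored_traits and j not in lead_cols:
                    lead_cols.append(j)
            while len(lead_cols) < config.leads_per_trait:
                j = int(rng.integers(0, m))
                if j not in lead_cols:
                    lead_cols.append(j)

        p = rng.uniform(0.0, 1.0, size=m)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        if i < config.anchored_traits and model_variant_cols:
            p[model_variant_cols] = 10.0 ** (
                -rng.uniform(8.5, 15.0, size=len(model_variant_cols))
            )
        for j in lead_cols:
            lo = (j // block) * block
            hi = min(lo + block, m)
            mates = [k for k in range(lo, hi) if k != j]
            p[mates] = 10.0 ** (-rng.uniform(4.5, 7.0, size=len(mates)))
            p[j] = 10.0 ** (-rng.uniform(8.5, 20.0))

        table = pd.DataFrame(
            {
                "variant_id": [v.id for v in panel.variants],
                "chrom": [v.chrom for v in panel.variants],
                "pos": [v.pos for v in panel.variants],
                "p": p,
            }
        )
        summaries.append(GwasSummary(trait=trait, table=table))
        leads = [panel.variants[j] for j in sorted(lead_cols)]
        catalogs.append(TraitCatalog(trait=trait, category=categories[trait], leads=leads))
        truth.trait_leads[trait] = [panel.variants[j].id for j in sorted(lead_cols)]
        truth.trait_categories[trait] = categories[trait]

    return summaries, catalogs
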