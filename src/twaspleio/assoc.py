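"""Association of imputed expression with case/control status.

Per gene and tissue, ordinary least squares of the binary status on
[intercept, GReX, sex, age, PC1, PC2]; the reported effect is the GReX
coefficient with its standard error and two-sided t-test p-value.  A
positive effect means predicted expression is higher in cases than in
controls.  P-values from ALL gene-tissue tests are adjusted jointly by
Benjamini-Hochberg, after genes in the MHC region (complex LD) and genes
with zero GReX variance have been removed so they do not inflate the test
count.  Linear regression on the 0/1 outcome is the primary model; a
logistic alternative is available behind a flag.

The per-gene fits are computed by residualising status and every GReX
column on the shared covariate design (Frisch-Waugh), which makes the
whole tissue a single matrix product; tests verify equality with a full
statsmodels OLS fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import GwasSummary, ValidationError, VariantKey, WeightModel
from .grex import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "pc1", "pc2")


@dataclass
class AnalysisConfig:
    """Thresholds and windows of the association stage."""

    q_threshold: float = 0.001
    mhc_chrom: str = "chr6"
    mhc_start: int = 28_477_797  # hg19
    mhc_end: int = 33_448_354
    gws_threshold: float = 5e-8
    suggestive_threshold: float = 1e-4
    locus_window: int = 1_000_000  # bp around a lead variant

    def __post_init__(self) -> None:
        for name in ("q_threshold", "gws_threshold", "suggestive_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.locus_window < 0:
            raise ValueError("locus_window must be >= 0")


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def _covariate_design(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for c in covariates:
        cols.append(cohort[c].to_numpy(dtype=float))
    Z = np.column_stack(cols)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        names = ["intercept", *covariates]
        collinear = [
            names[k]
            for k in range(Z.shape[1])
            if np.linalg.matrix_rank(np.delete(Z, k, axis=1)) == rank
        ]
        raise ValidationError(f"covariate design is rank-deficient; collinear columns: {collinear}")
    return Z


def run_association(
    expression: ExpressionMatrix,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    family: str = "linear",
) -> tuple[pd.DataFrame, list[str]]:
    """Regress status on GReX per gene, adjusting for the covariates.

    Returns ``(records, degenerate)``: a frame with columns gene, tissue,
    beta, se, p (one row per testable gene) and the list of genes excluded
    for zero GReX variance.  Sample order is taken from the expression
    matrix; the cohort must cover its sample ids.
    """
    cohort = cohort.set_index("sample_id", drop=False)
    missing = [s for s in expression.samples if s not in cohort.index]
    if missing:
        raise ValidationError(f"cohort lacks {len(missing)} expression samples (e.g. {missing[0]})")
    cohort = cohort.loc[expression.samples]
    n = len(expression.samples)
    y = cohort["status"].to_numpy(dtype=float)
    Z = _covariate_design(cohort, covariates)
    p_params = Z.shape[1] + 1  # + the GReX column
    if n < p_params + 1:
        raise ValidationError(f"need at least {p_params + 1} samples, got {n}")

    G = expression.values
    var = G.var(axis=0)
    degenerate_mask = var <= 1e-14
    degenerate = [g for g, d in zip(expression.genes, degenerate_mask) if d]
    if degenerate:
        logger.info("tissue %s: %d degenerate (zero-variance) genes excluded",
                    expression.tissue, len(degenerate))
    keep = ~degenerate_mask
    genes = [g for g, k in zip(expression.genes, keep) if k]
    G = G[:, keep]
    if not genes:
        empty = pd.DataFrame(columns=["gene", "tissue", "beta", "se", "p"])
        return empty, degenerate

    if family == "logistic":
        return _logistic_fits(genes, expression.tissue, G, y, Z), degenerate
    if family != "linear":
        raise ValueError(f"unknown family {family!r}")

    # Frisch-Waugh: residualise y and G on Z, then simple regression per gene.
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    denom = np.einsum("ij,ij->j", G_r, G_r)
    ok = denom > 1e-12
    if not ok.all():
        dropped = [g for g, o in zip(genes, ok) if not o]
        logger.info("tissue %s: %d genes collinear with covariates excluded",
                    expression.tissue, len(dropped))
        degenerate = degenerate + dropped
        genes = [g for g, o in zip(genes, ok) if o]
        G_r, denom = G_r[:, ok], denom[ok]
    beta = (G_r.T @ y_r) / denom
    rss = float(y_r @ y_r) - beta**2 * denom
    dof = n - p_params
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    pval = np.clip(pval, np.nextafter(0.0, 1.0), 1.0)
    records = pd.DataFrame(
        {"gene": genes, "tissue": expression.tissue, "beta": beta, "se": se, "p": pval}
    )
    return records, degenerate


def _logistic_fits(genes, tissue, G, y, Z) -> pd.DataFrame:
    import statsmodels.api as sm

    rows = []
    for j, g in enumerate(genes):
        X = np.column_stack([Z[:, :1], G[:, j], Z[:, 1:]])
        fit = sm.Logit(y, X).fit(disp=0)
        rows.append((g, tissue, fit.params[1], fit.bse[1], fit.pvalues[1]))
    return pd.DataFrame(rows, columns=["gene", "tissue", "beta", "se", "p"])


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.  Applied once,
    jointly, across all gene-tissue tests of the analysis.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_mhc_filter(
    records: pd.DataFrame, annotation: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Drop records of genes whose span intersects the MHC interval.

    Run BEFORE FDR so excluded genes do not count as tests.  Every gene in
    ``records`` must be annotated.
    """
    ann = annotation.set_index("gene")
    unknown = set(records["gene"]) - set(ann.index)
    if unknown:
        raise ValidationError(f"genes missing from annotation: {sorted(unknown)[:5]}")
    spans = ann.loc[records["gene"]]
    inside = (
        (spans["chrom"].to_numpy() == config.mhc_chrom)
        & (spans["start"].to_numpy() <= config.mhc_end)
        & (spans["end"].to_numpy() >= config.mhc_start)
    )
    n_genes_removed = records.loc[inside, "gene"].nunique()
    if n_genes_removed:
        logger.info("MHC filter removed %d genes (%d records)", n_genes_removed, int(inside.sum()))
    return records.loc[~inside].reset_index(drop=True)


def attach_q_values(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Joint BH adjustment over all records; adds q and significant columns."""
    out = records.copy()
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.array([], dtype=float)
    out["significant"] = out["q"] < config.q_threshold
    return out


# ---------------------------------------------------------------------------
# Annotation against the target-trait GWAS
# ---------------------------------------------------------------------------

def classify_locus(
    gene: str,
    annotation: pd.DataFrame,
    lead_variants: list[VariantKey],
    config: AnalysisConfig,
) -> str:
    """"known" if the gene span intersects lead +/- locus_window for any
    same-chromosome lead of the target trait, else "novel"."""
    row = annotation.loc[annotation["gene"] == gene]
    if row.empty:
        raise ValidationError(f"gene {gene} missing from annotation")
    chrom, start, end = row.iloc[0][["chrom", "start", "end"]]
    w = config.locus_window
    for lead in lead_variants:
        if lead.chrom == chrom and start <= lead.pos + w and end >= lead.pos - w:
            return "known"
    return "novel"


def annotate_model_variants(
    model: WeightModel, gwas: GwasSummary, config: AnalysisConfig
) -> tuple[int, int, int]:
    """Count a model's variants that are GWAS-significant for the target trait.

    Returns (n_model, n_gws with p <= 5e-8, n_suggestive with p < 1e-4);
    model variants absent from the summary count toward n_model only.
    """
    pmap = dict(zip(gwas.table["variant_id"], gwas.table["p"]))
    ps = [pmap[e.variant_id] for e in model.entries if e.variant_id in pmap]
    n_gws = sum(p <= config.gws_threshold for p in ps)
    n_sugg = sum(p < config.suggestive_threshold for p in ps)
    return len(model.entries), n_gws, n_sugg


def summarize_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary over all tissues in which the gene was testable.

    n_significant_tissues counts tissues with q below threshold; the
    strongest-effect tissue maximises |beta| over ALL the gene's records
    (ties: smaller p, then lexicographic tissue name).
    """
    rows = []
    for gene, grp in records.groupby("gene", sort=True):
        ordered = grp.sort_values(
            by=["beta", "p", "tissue"],
            key=lambda s: -s.abs() if s.name == "beta" else s,
            kind="mergesort",
        )
        top = ordered.iloc[0]
        rows.append(
            {
                "gene": gene,
                "n_significant_tissues": int(grp["significant"].sum()),
                "strongest_effect_tissue": top["tissue"],
                "strongest_beta": float(top["beta"]),
            }
        )
    return pd.DataFrame(rows, columns=[
        "gene", "n_significant_tissues", "strongest_effect_tissue", "strongest_beta"
    ])
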