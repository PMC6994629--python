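"""End-to-end orchestration: simulate -> impute -> associate -> pleiotropy.

One config drives the whole analysis; every stage's inputs and outputs are
written to the output directory so each stage can also be re-run standalone
from the library API.  The run report collects the bookkeeping counts the
analysis is judged by — tests run, genes excluded in the MHC region,
significant gene-tissue pairs, unique significant genes and their
known/novel locus split, locus-overlap and pleiotropy counts — together
with the percentages derived from them (rounded half-up, matching how such
ratios are conventionally printed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, formats, grex, pleio, synthio

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene", "tissue", "beta", "se", "p", "q", "significant",
    "n_model_variants", "n_gws_variants", "n_suggestive_variants", "locus_class",
]


def compute_report_percentages(numerator: int, denominator: int, decimals: int = 2):
    """100 * numerator / denominator, rounded half-up; None when undefined."""
    if denominator == 0:
        return None
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Simulation + analysis settings for a full synthetic run."""

    simulation: synthio.SimulationConfig = field(default_factory=synthio.SimulationConfig)
    analysis: assoc.AnalysisConfig = field(default_factory=assoc.AnalysisConfig)
    gmt_path: str | None = None  # optional gene-set library for enrichment
    n_random_lists: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"simulation", "analysis", "gmt_path", "n_random_lists"}
        if unknown:
            raise formats.FormatError(f"{path}: unknown config sections {sorted(unknown)}")
        sim = synthio.SimulationConfig.from_dict(raw.get("simulation", {}))
        ana_raw = raw.get("analysis", {})
        bad = set(ana_raw) - set(assoc.AnalysisConfig.__dataclass_fields__)
        if bad:
            raise formats.FormatError(f"{path}: unknown analysis fields {sorted(bad)}")
        ana = assoc.AnalysisConfig(**ana_raw)
        return cls(
            simulation=sim,
            analysis=ana,
            gmt_path=raw.get("gmt_path"),
            n_random_lists=raw.get("n_random_lists", 100),
        )


@dataclass
class RunReport:
    """Machine-readable bookkeeping of one pipeline run."""

    seed: int
    n_tests: int
    n_genes_mhc_excluded: int
    n_degenerate_genes: int
    n_significant_pairs: int
    n_unique_significant_genes: int
    n_known_locus_genes: int
    n_novel_locus_genes: int
    n_predictable_genes: int
    n_significant_in_r2_loci: int
    n_significant_pleiotropic: int
    n_predictable_in_r2_loci: int
    n_significant_in_1mb_loci: int
    n_predictable_in_1mb_loci: int
    pct_significant_in_r2_loci: float | None
    pct_significant_pleiotropic: float | None
    pct_predictable_in_r2_loci: float | None
    pct_significant_in_1mb_loci: float | None
    pct_predictable_in_1mb_loci: float | None
    tissue_count_mwu_p: float | None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_unique_significant_genes <= self.n_significant_pairs
        assert (
            self.n_known_locus_genes + self.n_novel_locus_genes
            == self.n_unique_significant_genes
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_all(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    force: bool = False,
    write_inputs: bool = True,
) -> RunReport:
    """Run the full synthetic analysis and write all artifacts to ``out_dir``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    sim = config.simulation
    if seed is not None:
        sim = dataclasses.replace(sim, seed=seed)
    ana = config.analysis

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    logger.info("stage=simulate seed=%d", sim.seed)
    panel = synthio.simulate_genotypes(sim)
    annotation = synthio.simulate_gene_annotation(sim, panel)
    models, truth = synthio.simulate_weight_models(sim, panel, annotation)
    cohort = synthio.simulate_cohort(sim, panel, models, truth)
    summaries, catalogs = synthio.simulate_gwas_catalogs(
        sim, panel, truth, models=models, annotation=annotation
    )

    if write_inputs:
        formats.write_dosage_vcf(panel, out / "dosages.vcf")
        formats.write_weight_table(models, out / "weights.tsv")
        formats.write_cohort_table(cohort, out / "cohort.tsv")
        formats.write_gene_annotation(annotation, out / "genes.tsv")
        for s in summaries:
            formats.write_gwas_summary(s, out / f"gwas_{s.trait}.tsv")
        formats.write_category_map(
            {c.trait: c.category for c in catalogs}, out / "categories.tsv"
        )
        with open(out / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(
                {
                    "causal_alpha": truth.causal_alpha,
                    "causal_tissue": truth.causal_tissue,
                    "trait_leads": truth.trait_leads,
                    "trait_categories": truth.trait_categories,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    # --- impute and associate ----------------------------------------------
    filled = grex.fill_missing_dosages(panel)
    tissues = sorted({m.tissue for m in models})
    all_records = []
    degenerate: set[str] = set()
    predictable_genes: set[str] = set()
    for tissue in tissues:
        logger.info("stage=impute tissue=%s", tissue)
        expr = grex.impute_expression(filled, models, tissue)
        predictable_genes.update(expr.genes)
        recs, degen = assoc.run_association(expr, cohort)
        degenerate.update(degen)
        all_records.append(recs)
    records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame(
        columns=["gene", "tissue", "beta", "se", "p"]
    )

    n_before = records["gene"].nunique()
    records = assoc.apply_mhc_filter(records, annotation, ana)
    n_mhc_excluded = n_before - records["gene"].nunique()
    records = assoc.attach_q_values(records, ana)

    # --- annotate against the target-trait GWAS -----------------------------
    amd = next(s for s in summaries if s.trait == catalogs[0].trait)
    amd_leads = catalogs[0].leads
    model_by_key = {(m.tissue, m.gene): m for m in models}
    counts = [
        assoc.annotate_model_variants(model_by_key[(t, g)], amd, ana)
        for t, g in zip(records["tissue"], records["gene"])
    ]
    records["n_model_variants"] = [c[0] for c in counts]
    records["n_gws_variants"] = [c[1] for c in counts]
    records["n_suggestive_variants"] = [c[2] for c in counts]
    locus_class = {
        g: assoc.classify_locus(g, annotation, amd_leads, ana)
        for g in records["gene"].unique()
    }
    records["locus_class"] = records["gene"].map(locus_class)
    records[RESULT_COLUMNS].to_csv(out / "results.tsv", sep="\t", index=False, lineterminator="\n")

    gene_summary = assoc.summarize_genes(records)
    sig = records[records["significant"]]
    sig_genes = set(sig["gene"].unique())
    n_known = sum(1 for g in sig_genes if locus_class[g] == "known")
    n_novel = len(sig_genes) - n_known

    # --- pleiotropy ----------------------------------------------------------
    logger.info("stage=pleiotropy traits=%d", len(catalogs))
    raw_loci = pleio.build_trait_loci(panel, catalogs)
    merged = pleio.merge_loci(raw_loci)
    extended = pleio.extend_loci(raw_loci, ana.locus_window)
    formats.write_locus_bed(merged, out / "loci_r2.bed")
    formats.write_locus_bed(extended, out / "loci_1mb.bed")

    overlap = pleio.overlap_genes(merged, annotation)
    overlap_1mb = pleio.overlap_genes(extended, annotation)
    gene_summary["in_any_locus"] = [
        overlap.in_any_locus.get(g, False) for g in gene_summary["gene"]
    ]
    gene_summary["pleiotropic"] = [
        overlap.pleiotropic.get(g, False) for g in gene_summary["gene"]
    ]
    gene_summary["locus_class"] = gene_summary["gene"].map(locus_class)
    gene_summary.to_csv(out / "gene_summary.tsv", sep="\t", index=False, lineterminator="\n")

    ov_rows = [
        (g, ";".join(sorted(cats)), overlap.in_any_locus[g], overlap.pleiotropic[g])
        for g, cats in sorted(overlap.categories.items())
    ]
    pd.DataFrame(
        ov_rows, columns=["gene", "categories", "in_any_locus", "pleiotropic"]
    ).to_csv(out / "gene_overlap.tsv", sep="\t", index=False, lineterminator="\n")

    all_categories = sorted({c.category for c in catalogs})
    enr_rows = []
    for cat in all_categories:
        a, b, c_, d, odds, p = pleio.category_enrichment(
            sig_genes & predictable_genes, predictable_genes, overlap, cat
        )
        enr_rows.append((cat, a, b, c_, d, odds, p))
    pd.DataFrame(
        enr_rows, columns=["category", "a", "b", "c", "d", "odds_ratio", "p"]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")

    try:
        _, mwu_p = pleio.tissue_count_comparison(gene_summary, overlap)
    except formats.ValidationError:
        mwu_p = None

    # --- optional gene-set enrichment ---------------------------------------
    if config.gmt_path:
        from . import enrich as _enrich

        sets = formats.read_gmt(config.gmt_path)
        table = _enrich.enrich_terms(
            sig_genes & predictable_genes, sets, predictable_genes,
            n_random_lists=config.n_random_lists, seed=sim.seed,
        )
        table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False, lineterminator="\n")

    # --- report --------------------------------------------------------------
    n_sig_in_r2 = sum(1 for g in sig_genes if overlap.in_any_locus.get(g, False))
    n_sig_pleio = sum(1 for g in sig_genes if overlap.pleiotropic.get(g, False))
    n_pred_in_r2 = sum(1 for g in predictable_genes if overlap.in_any_locus.get(g, False))
    n_sig_in_1mb = sum(1 for g in sig_genes if overlap_1mb.in_any_locus.get(g, False))
    n_pred_in_1mb = sum(1 for g in predictable_genes if overlap_1mb.in_any_locus.get(g, False))
    report = RunReport(
        seed=sim.seed,
        n_tests=len(records),
        n_genes_mhc_excluded=n_mhc_excluded,
        n_degenerate_genes=len(degenerate),
        n_significant_pairs=len(sig),
        n_unique_significant_genes=len(sig_genes),
        n_known_locus_genes=n_known,
        n_novel_locus_genes=n_novel,
        n_predictable_genes=len(predictable_genes),
        n_significant_in_r2_loci=n_sig_in_r2,
        n_significant_pleiotropic=n_sig_pleio,
        n_predictable_in_r2_loci=n_pred_in_r2,
        n_significant_in_1mb_loci=n_sig_in_1mb,
        n_predictable_in_1mb_loci=n_pred_in_1mb,
        pct_significant_in_r2_loci=compute_report_percentages(n_sig_in_r2, len(sig_genes)),
        pct_significant_pleiotropic=compute_report_percentages(n_sig_pleio, len(sig_genes)),
        pct_predictable_in_r2_loci=compute_report_percentages(
            n_pred_in_r2, len(predictable_genes)
        ),
        pct_significant_in_1mb_loci=compute_report_percentages(n_sig_in_1mb, len(sig_genes)),
        pct_predictable_in_1mb_loci=compute_report_percentages(
            n_pred_in_1mb, len(predictable_genes)
        ),
        tissue_count_mwu_p=mwu_p,
        config={"simulation": sim.to_dict(), "analysis": dataclasses.asdict(ana)},
    )
    report.to_json(out / "report.json")
    return report
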