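"""External representations of the pipeline's inputs and outputs.

Every stage of the analysis exchanges data through a small set of typed
containers: a dosage panel (samples x variants effect-allele dosages in
[0, 2]), per-tissue expression-prediction weight models, a cohort table of
phenotype and covariates, GWAS summary statistics, gene annotations, locus
intervals and gene sets.  This module defines those containers and the
readers/writers for their on-disk forms (VCF with a per-sample dosage
field, tab-separated tables with fixed headers, BED, GMT).

Coordinate convention: all in-memory positions are 1-based inclusive.
Only the BED reader/writer converts to and from 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant (e.g. dosage > 2)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic variant: position plus allele pair."""

    chrom: str
    pos: int  # 1-based bp
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"variant {self.id}: ref and alt alleles are identical")


@dataclass
class DosagePanel:
    """Samples x variants matrix of effect(alt)-allele dosages in [0, 2].

    Missing dosages are NaN, never 0: filling missing genotypes is an
    explicit, separate step of the analysis.
    """

    variants: list[VariantKey]
    samples: list[str]
    dosages: np.ndarray  # shape (n_samples, n_variants), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in panel")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate variant ids in panel")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} outside [0, 2] "
                f"(sample {self.samples[i]}, variant {self.variants[j].id})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        """Map variant id -> column index."""
        return {v.id: j for j, v in enumerate(self.variants)}

    def position_index(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> column index (first occurrence wins)."""
        out: dict[tuple[str, int], int] = {}
        for j, v in enumerate(self.variants):
            out.setdefault((v.chrom, v.pos), j)
        return out


@dataclass
class WeightEntry:
    """One (variant, effect allele, weight) term of a prediction model."""

    variant_id: str
    effect_allele: str
    non_effect_allele: str
    weight: float


@dataclass
class WeightModel:
    """Sparse cis-eQTL prediction model for one gene in one tissue."""

    tissue: str
    gene: str
    entries: list[WeightEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"model {self.tissue}/{self.gene}: no entries")
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"model {self.tissue}/{self.gene}: duplicate variant")


@dataclass
class GwasSummary:
    """Per-trait GWAS summary statistics (variant, position, p-value)."""

    trait: str
    table: pd.DataFrame  # columns: variant_id, chrom, pos, p

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError(f"trait {self.trait}: p-values must lie in (0, 1]")


@dataclass
class Locus:
    """A genomic interval (1-based inclusive) tagged with traits/categories."""

    chrom: str
    start: int
    end: int
    traits: frozenset[str] = field(default_factory=frozenset)
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"locus {self.chrom}:{self.start}-{self.end}: start > end")
        self.traits = frozenset(self.traits)
        self.categories = frozenset(self.categories)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneSet:
    """One GMT record: a named gene set with a free-text description."""

    term: str
    description: str
    genes: list[str]


COHORT_COLUMNS = ["sample_id", "status", "sex", "age", "pc1", "pc2"]
WEIGHT_COLUMNS = ["tissue", "gene", "variant_id", "effect_allele", "non_effect_allele", "weight"]
GWAS_COLUMNS = ["variant_id", "chrom", "pos", "p"]
GENE_COLUMNS = ["gene", "chrom", "start", "end"]


# ---------------------------------------------------------------------------
# VCF dosage panel
# ---------------------------------------------------------------------------

def read_dosage_vcf(path: str | Path, dosage_field: str = "DS") -> DosagePanel:
    """Read a VCF with a per-sample numeric dosage FORMAT field into a panel.

    Multi-allelic records are rejected; missing dosages become NaN; dosages
    outside [0, 2] raise :class:`ValidationError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"{path}: cannot parse VCF ({exc})") from exc
    samples = list(vcf.samples)
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    for line_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: record {line_no} ({rec.CHROM}:{rec.POS}) is not biallelic"
            )
        ds = rec.format(dosage_field)
        if ds is None:
            raise FormatError(
                f"{path}: record {line_no} ({rec.CHROM}:{rec.POS}) lacks FORMAT field "
                f"{dosage_field!r}"
            )
        col = np.asarray(ds, dtype=float).reshape(len(samples))
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(VariantKey(rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0]))
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=float)
    )
    return DosagePanel(variants=variants, samples=samples, dosages=dosages)


def write_dosage_vcf(panel: DosagePanel, path: str | Path, dosage_field: str = "DS") -> None:
    """Write a panel as a minimal VCF with one float FORMAT field per sample."""
    chroms = list(dict.fromkeys(v.chrom for v in panel.variants))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##FORMAT=<ID={dosage_field},Number=1,Type=Float,'
            f'Description="Effect allele dosage">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, v in enumerate(panel.variants):
            vals = [
                "." if math.isnan(d) else format(d, ".6g") for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\t{dosage_field}\t" + "\t".join(vals) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate table (status, sex, age, pc1, pc2)."""
    df = _read_tsv(path, COHORT_COLUMNS)
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    if not df["status"].isin([0, 1]).all():
        raise ValidationError(f"{path}: status must be 0 (control) or 1 (case)")
    return df[COHORT_COLUMNS].copy()


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_weight_table(path: str | Path) -> list[WeightModel]:
    """Read a PredictDB-style weight TSV into one model per (tissue, gene)."""
    df = _read_tsv(path, WEIGHT_COLUMNS)
    if df.empty:
        return []
    try:
        weights = df["weight"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric weight ({exc})") from exc
    df = df.assign(weight=weights)
    dup = df.duplicated(subset=["tissue", "gene", "variant_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate weight row for "
            f"({row['tissue']}, {row['gene']}, {row['variant_id']})"
        )
    models = []
    for (tissue, gene), grp in df.groupby(["tissue", "gene"], sort=True):
        entries = [
            WeightEntry(r.variant_id, r.effect_allele, r.non_effect_allele, r.weight)
            for r in grp.itertuples()
        ]
        models.append(WeightModel(tissue=str(tissue), gene=str(gene), entries=entries))
    return models


def write_weight_table(models: Iterable[WeightModel], path: str | Path) -> None:
    rows = [
        (m.tissue, m.gene, e.variant_id, e.effect_allele, e.non_effect_allele, e.weight)
        for m in models
        for e in m.entries
    ]
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gwas_summary(path: str | Path, trait: str) -> GwasSummary:
    """Read one trait's GWAS summary statistics TSV."""
    df = _read_tsv(path, GWAS_COLUMNS)
    df = df[GWAS_COLUMNS].copy()
    df["pos"] = df["pos"].astype(int)
    df["p"] = df["p"].astype(float)
    return GwasSummary(trait=trait, table=df)


def write_gwas_summary(summary: GwasSummary, path: str | Path) -> None:
    summary.table[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene spans (gene, chrom, start, end; 1-based inclusive)."""
    df = _read_tsv(path, GENE_COLUMNS)
    df = df[GENE_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValidationError(f"{path}: gene {bad['gene']} has start > end")
    if df["gene"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return df


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[GENE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read the trait -> category assignment TSV (columns: trait, category)."""
    df = _read_tsv(path, ["trait", "category"])
    return dict(zip(df["trait"].astype(str), df["category"].astype(str)))


def write_category_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["trait", "category"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# BED (the only 0-based half-open surface)
# ---------------------------------------------------------------------------

def write_locus_bed(loci: Iterable[Locus], path: str | Path) -> None:
    """Write loci as BED: 0-based half-open, name = traits|categories."""
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for loc in ordered:
            name = ";".join(sorted(loc.traits)) + "|" + ";".join(sorted(loc.categories))
            fh.write(f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{name}\n")


def read_locus_bed(path: str | Path) -> list[Locus]:
    loci = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: BED line needs >= 3 fields")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            traits: frozenset[str] = frozenset()
            categories: frozenset[str] = frozenset()
            if len(parts) >= 4 and "|" in parts[3]:
                t, c = parts[3].split("|", 1)
                traits = frozenset(x for x in t.split(";") if x)
                categories = frozenset(x for x in c.split(";") if x)
            loci.append(Locus(chrom, start0 + 1, end, traits, categories))
    return loci


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: term <tab> description <tab> gene [<tab> gene ...]."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{line_no}: GMT line needs term, description and >=1 gene"
                )
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write(s.term + "\t" + s.description + "\t" + "\t".join(s.genes) + "\n")
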