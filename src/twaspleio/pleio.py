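"""Cross-trait pleiotropy via LD-defined R-squared loci.

For each trait's genome-wide-significant lead variant, the locus is the
genomic interval spanned by every reference-panel variant whose squared
dosage correlation with the lead exceeds 0.5 (the lead itself always
qualifies).  Overlapping loci — across traits — are merged transitively
into candidate pleiotropic regions carrying the union of their traits and
categories; an optional 1 Mb extension on both sides reproduces the wider,
prediction-window-matched locus definition.  Genes are assigned to every
category whose locus their span intersects; a gene is potentially
pleiotropic when it touches two or more distinct categories.  Whether the
target-trait gene list is enriched in a category's loci is judged by a
two-sided Fisher exact test against the full predictable-gene universe,
and the number of significant tissues per gene is compared between
in-locus and out-of-locus genes by a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import DosagePanel, Locus, ValidationError, VariantKey


@dataclass
class TraitCatalog:
    """One trait's independent genome-wide-significant lead variants."""

    trait: str
    category: str
    leads: list[VariantKey]


@dataclass
class OverlapTable:
    """Per-gene category assignment from locus overlap."""

    categories: dict[str, set[str]]  # gene -> categories overlapped
    in_any_locus: dict[str, bool] = field(default_factory=dict)
    pleiotropic: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, cats in self.categories.items():
            self.in_any_locus[g] = bool(cats)
            self.pleiotropic[g] = len(cats) >= 2


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(panel: DosagePanel, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of two variants' dosage vectors.

    Defined as 0 when either vector is constant.
    """
    idx = panel.variant_index()
    for v in (variant_a, variant_b):
        if v not in idx:
            raise ValidationError(f"variant {v} absent from panel")
    if panel.n_samples < 2:
        raise ValidationError("LD needs at least 2 samples")
    x = panel.dosages[:, idx[variant_a]]
    y = panel.dosages[:, idx[variant_b]]
    return _r2(x, y)


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return min(r * r, 1.0)


def build_r2_locus(
    panel: DosagePanel,
    lead: VariantKey,
    trait: str = "",
    category: str = "",
    r2_threshold: float = 0.5,
    search_window_bp: int = 2_000_000,
) -> Locus:
    """Locus spanned by all panel variants linked to the lead (r^2 > 0.5).

    Only variants on the lead's chromosome within ``search_window_bp`` of
    it are examined; the threshold is strict, and the lead itself (r^2 = 1)
    always defines at least a single-position locus.
    """
    idx = panel.variant_index()
    if lead.id not in idx:
        raise ValidationError(f"lead variant {lead.id} absent from panel")
    lead_col = panel.dosages[:, idx[lead.id]]
    lo, hi = lead.pos, lead.pos
    for j, v in enumerate(panel.variants):
        if v.chrom != lead.chrom or abs(v.pos - lead.pos) > search_window_bp:
            continue
        if v.id == lead.id or _r2(lead_col, panel.dosages[:, j]) > r2_threshold:
            lo = min(lo, v.pos)
            hi = max(hi, v.pos)
    traits = frozenset({trait}) if trait else frozenset()
    cats = frozenset({category}) if category else frozenset()
    return Locus(lead.chrom, lo, hi, traits, cats)


def build_trait_loci(
    panel: DosagePanel,
    catalogs: list[TraitCatalog],
    r2_threshold: float = 0.5,
    search_window_bp: int = 2_000_000,
) -> list[Locus]:
    """One R-squared locus per lead of every trait catalog (unmerged)."""
    loci = []
    for cat in catalogs:
        for lead in cat.leads:
            loci.append(
                build_r2_locus(panel, lead, cat.trait, cat.category, r2_threshold, search_window_bp)
            )
    return loci


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_loci(loci: list[Locus]) -> list[Locus]:
    """Transitively merge per-chromosome loci sharing at least one bp.

    Coordinates are 1-based inclusive, so [100, 200] and [200, 300] merge.
    The merged locus carries the union of traits and categories; output is
    sorted by (chrom, start).
    """
    out: list[Locus] = []
    by_chrom: dict[str, list[Locus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end))
        cur_start, cur_end = group[0].start, group[0].end
        traits, cats = set(group[0].traits), set(group[0].categories)
        for loc in group[1:]:
            if loc.start <= cur_end + 0:  # inclusive: touching at one bp overlaps
                cur_end = max(cur_end, loc.end)
                traits |= loc.traits
                cats |= loc.categories
            else:
                out.append(Locus(chrom, cur_start, cur_end, frozenset(traits), frozenset(cats)))
                cur_start, cur_end = loc.start, loc.end
                traits, cats = set(loc.traits), set(loc.categories)
        out.append(Locus(chrom, cur_start, cur_end, frozenset(traits), frozenset(cats)))
    return out


def extend_loci(loci: list[Locus], window_bp: int = 1_000_000) -> list[Locus]:
    """Expand each locus by ``window_bp`` on both sides (start clamped at 1),
    then merge overlaps."""
    widened = [
        Locus(l.chrom, max(1, l.start - window_bp), l.end + window_bp, l.traits, l.categories)
        for l in loci
    ]
    return merge_loci(widened)


def overlap_genes(loci: list[Locus], annotation: pd.DataFrame) -> OverlapTable:
    """Assign every gene the categories of every locus its span intersects."""
    by_chrom: dict[str, list[Locus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    categories: dict[str, set[str]] = {}
    for row in annotation.itertuples():
        cats: set[str] = set()
        for loc in by_chrom.get(row.chrom, []):
            if row.start <= loc.end and row.end >= loc.start:
                cats |= loc.categories
        categories[row.gene] = cats
    return OverlapTable(categories=categories)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def category_enrichment(
    target_genes: set[str],
    all_predictable_genes: set[str],
    overlap: OverlapTable,
    category: str,
) -> tuple[int, int, int, int, float, float]:
    """Two-sided Fisher exact test of target-gene overlap with a category.

    2x2 table rows are {target genes, other predictable genes}, columns
    {overlaps a locus of the category, does not}.  Returns
    (a, b, c, d, odds_ratio, p).  The two-sided p sums all hypergeometric
    tables with point probability <= the observed one; degenerate margins
    give p = 1.
    """
    if not target_genes <= all_predictable_genes:
        raise ValidationError("target genes must be a subset of the predictable universe")
    hits = {g for g, cats in overlap.categories.items() if category in cats}
    a = len(target_genes & hits)
    b = len(target_genes - hits)
    other = all_predictable_genes - target_genes
    c = len(other & hits)
    d = len(other - hits)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        odds = np.inf if (b == 0 or c == 0) and (a or d) else np.nan
        return a, b, c, d, float(odds), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return a, b, c, d, float(odds), float(p)


def tissue_count_comparison(
    gene_summaries: pd.DataFrame, overlap: OverlapTable
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on significant-tissue counts, in-locus vs not.

    Exact null by enumeration when the combined sample size is at most 25
    and there are no ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    counts = gene_summaries.set_index("gene")["n_significant_tissues"]
    in_locus = [counts[g] for g in counts.index if overlap.in_any_locus.get(g, False)]
    out_locus = [counts[g] for g in counts.index if not overlap.in_any_locus.get(g, False)]
    if not in_locus or not out_locus:
        raise ValidationError("both gene groups must be non-empty for the comparison")
    combined = in_locus + out_locus
    no_ties = len(set(combined)) == len(combined)
    method = "exact" if (len(combined) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        in_locus, out_locus, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
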