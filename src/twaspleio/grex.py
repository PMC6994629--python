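"""Genetically regulated expression (GReX) imputation.

GReX for sample i and gene g is the plain weighted sum over the gene's
prediction-model variants of the harmonized effect-allele dosage:

    GReX[i, g] = sum_k w_k * d_eff[i, k]

where d_eff is the panel dosage if the model's effect allele is the panel
alt allele, and 2 - dosage if effect and non-effect alleles are swapped
relative to the panel.  Entries whose allele pair is incompatible with the
panel's, or whose variant is absent from the panel, are dropped and
counted.  No intercept or normalisation is applied: association downstream
is scale-equivariant, so p-values are unaffected.

The panel must be complete before imputation; ``fill_missing_dosages``
replaces each missing cell by the variant's modal hard genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import DosagePanel, ValidationError, VariantKey, WeightEntry, WeightModel

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Samples x genes imputed expression for one tissue."""

    tissue: str
    samples: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValidationError("expression matrix shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")


def fill_missing_dosages(panel: DosagePanel) -> DosagePanel:
    """Replace missing dosages by the variant's most frequent hard genotype.

    Non-missing dosages are rounded half-up to {0, 1, 2} only to determine
    the mode; observed cells are returned unchanged.  Ties break to the
    lower genotype.  A variant with no observed dosage at all is an error.
    """
    d = panel.dosages
    missing = np.isnan(d)
    if not missing.any():
        return panel
    all_missing = missing.all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        raise ValidationError(
            f"variant {panel.variants[j].id}: all dosages missing, no modal genotype"
        )
    filled = d.copy()
    # round half-up: floor(d + 0.5); dosages are in [0, 2] so no clipping needed
    hard = np.floor(d + 0.5)
    for j in np.nonzero(missing.any(axis=0))[0]:
        col = hard[:, j]
        counts = [(col == g).sum() for g in (0.0, 1.0, 2.0)]
        mode = float(int(np.argmax(counts)))  # argmax takes the first (lowest) on ties
        filled[missing[:, j], j] = mode
    return DosagePanel(variants=panel.variants, samples=panel.samples, dosages=filled)


def harmonize_alleles(entry: WeightEntry, variant: VariantKey) -> tuple[float, float] | None:
    """Map a model entry onto the panel's alt-dosage scale.

    Returns ``(sign, offset)`` such that the effect-allele dosage equals
    ``sign * d + offset`` for panel alt-dosage ``d``: identity ``(1, 0)``
    when effect = alt, complement ``(-1, 2)`` when effect = ref and
    non-effect = alt, and ``None`` (entry dropped) for any other allele
    pair.
    """
    if entry.effect_allele == variant.alt_allele and entry.non_effect_allele == variant.ref_allele:
        return (1.0, 0.0)
    if entry.effect_allele == variant.ref_allele and entry.non_effect_allele == variant.alt_allele:
        return (-1.0, 2.0)
    return None


def impute_expression(
    panel: DosagePanel,
    models: Sequence[WeightModel],
    tissue: str,
) -> ExpressionMatrix:
    """Impute GReX for every gene of ``tissue`` present in the panel.

    value[i, g] = sum over the gene's harmonized entries of
    weight * effect-allele dosage.  Genes none of whose model variants are
    in the panel are omitted (and logged); incompatible-allele entries are
    dropped (and counted).  The panel must contain no missing dosages.
    """
    tissue_models = [m for m in models if m.tissue == tissue]
    if not tissue_models:
        raise ValidationError(f"tissue {tissue!r} absent from the supplied models")
    if np.isnan(panel.dosages).any():
        raise ValidationError("panel contains missing dosages; run fill_missing_dosages first")

    vindex = panel.variant_index()
    n = panel.n_samples
    genes: list[str] = []
    cols: list[np.ndarray] = []
    n_dropped_alleles = 0
    n_absent = 0
    for model in tissue_models:
        acc = np.zeros(n, dtype=float)
        used = 0
        for e in model.entries:
            j = vindex.get(e.variant_id)
            if j is None:
                n_absent += 1
                continue
            tr = harmonize_alleles(e, panel.variants[j])
            if tr is None:
                n_dropped_alleles += 1
                logger.warning(
                    "model %s/%s: entry %s alleles (%s/%s) incompatible with panel "
                    "(%s/%s); entry dropped",
                    model.tissue, model.gene, e.variant_id,
                    e.effect_allele, e.non_effect_allele,
                    panel.variants[j].ref_allele, panel.variants[j].alt_allele,
                )
                continue
            sign, offset = tr
            acc += e.weight * (sign * panel.dosages[:, j] + offset)
            used += 1
        if used == 0:
            logger.warning(
                "model %s/%s: no model variant present in panel; gene omitted",
                model.tissue, model.gene,
            )
            continue
        genes.append(model.gene)
        cols.append(acc)
    if n_absent or n_dropped_alleles:
        logger.info(
            "tissue %s: %d entries absent from panel, %d dropped for allele mismatch",
            tissue, n_absent, n_dropped_alleles,
        )
    values = np.column_stack(cols) if cols else np.empty((n, 0), dtype=float)
    return ExpressionMatrix(tissue=tissue, samples=list(panel.samples), genes=genes, values=values)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write a sample x gene expression matrix as TSV with gene-id header."""
    import pandas as pd

    df = pd.DataFrame(expr.values, columns=expr.genes)
    df.insert(0, "sample_id", expr.samples)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
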