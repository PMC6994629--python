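import numpy as np
import pytest

from twaspleio.formats import DosagePanel, VariantKey, WeightEntry, WeightModel


def make_panel(dosages, positions=None, chrom="chr1", ref="A", alt="G"):
    """Build a small panel from a (samples x variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    variants = [VariantKey(chrom, positions[j], f"v{j}", ref, alt) for j in range(m)]
    samples = [f"S{i}" for i in range(n)]
    return DosagePanel(variants=variants, samples=samples, dosages=dosages)


def make_model(weights, tissue="t0", gene="G0", effect="alt", ref="A", alt="G"):
    """Model over variants v0..v{k-1} with the given weights (effect = alt)."""
    entries = []
    for j, w in enumerate(weights):
        if effect == "alt":
            entries.append(WeightEntry(f"v{j}", alt, ref, float(w)))
        else:
            entries.append(WeightEntry(f"v{j}", ref, alt, float(w)))
    return WeightModel(tissue=tissue, gene=gene, entries=entries)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
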