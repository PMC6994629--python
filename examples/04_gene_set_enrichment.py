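"""Overrepresentation of a gene list against a small GMT library.

Computes the hypergeometric upper-tail p, BH adjustment, the rank-deviation
z-score against random queries, and the combined score ln(p) * z.
"""

from twaspleio import GeneSet, enrich_terms

background = {f"GENE{i:03d}" for i in range(200)}
ordered = sorted(background)
query = set(ordered[:15])

library = [
    GeneSet("complement_like", "engineered hit", ordered[:20]),
    GeneSet("lipid_like", "partial hit", ordered[10:40]),
    GeneSet("unrelated_a", "null", ordered[100:140]),
    GeneSet("unrelated_b", "null", ordered[150:190]),
]

table = enrich_terms(query, library, background, n_random_lists=100, seed=0)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# Small p + negative z_rank (better-than-expected rank) give a large
# positive combined score; null terms sit near p = 1 and score ~ 0.
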