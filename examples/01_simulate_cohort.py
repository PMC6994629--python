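"""Simulate a genotyped case/control cohort with known causal genes.

Builds LD-blocked dosages, sparse cis weight models for 2 tissues, and a
liability-threshold phenotype, then prints what the truth set contains.
"""

from twaspleio import SimulationConfig, simulate_cohort, simulate_gene_annotation, \
    simulate_genotypes, simulate_weight_models

cfg = SimulationConfig(n_samples=1000, n_variants=400, n_genes=40, n_tissues=2,
                       n_causal_genes=4, seed=1)
panel = simulate_genotypes(cfg)
annotation = simulate_gene_annotation(cfg, panel)
models, truth = simulate_weight_models(cfg, panel, annotation)
cohort = simulate_cohort(cfg, panel, models, truth)

print(f"panel: {panel.n_samples} samples x {panel.n_variants} variants")
print(f"models: {len(models)} gene-tissue weight sets")
print(f"cases: {int(cohort.status.sum())} of {len(cohort)} (prevalence {cfg.prevalence})")
print("causal genes (liability effect per unit GReX):")
for gene, alpha in truth.causal_alpha.items():
    print(f"  {gene}: alpha = {alpha:+.2f}")
# alpha > 0 means the gene's genetic expression component raises disease
# liability, so its predicted expression should be higher in cases.
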