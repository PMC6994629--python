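"""Run the whole analysis from one config and read the run report.

Equivalent to `twaspleio run --out OUT --seed 7`.
"""

import json

from twaspleio import PipelineConfig, run_all

report = run_all(PipelineConfig(), "example_run", seed=7, force=True)
print(f"tests run:                {report.n_tests}")
print(f"significant pairs:        {report.n_significant_pairs}")
print(f"unique significant genes: {report.n_unique_significant_genes} "
      f"(known {report.n_known_locus_genes} + novel {report.n_novel_locus_genes})")
print(f"in any R^2 locus:         {report.n_significant_in_r2_loci} "
      f"({report.pct_significant_in_r2_loci}%)")
print(f"tissue-count MWU p:       {report.tissue_count_mwu_p:.3g}")
# All artifacts (results.tsv, gene_summary.tsv, loci_*.bed, gene_overlap.tsv,
# enrichment.tsv, report.json) are in example_run/.
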