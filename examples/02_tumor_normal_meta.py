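"""Tumor-vs-normal meta-analysis: per-study Hedges' g pooled per gene.

Studies need at least 10 samples in each group; genes need at least three
qualifying studies.  The forest table shows the per-study estimates behind
one pooled summary.
"""

import numpy as np
import pandas as pd

from metacohort import (SyntheticConfig, generate_cohort, smd_table,
                        meta_table, random_effects_meta, forest_data)

rng = np.random.default_rng(1)
config = SyntheticConfig(n_studies=8, genes=300,
                         true_smd=rng.normal(0, 0.5, 300), seed=21)
bundles, truth = generate_cohort(config)

estimates = pd.concat([smd_table(b) for b in bundles], ignore_index=True)
results = meta_table(estimates, "SMD")
print(f"{len(results)} genes meta-analyzed over up to {len(bundles)} studies")

top = results.sort_values("summary", ascending=False).head(3)
print("\nmost upregulated genes (summary = pooled SMD, tumor minus normal):")
print(top[["gene_id", "k", "summary", "ci_low", "ci_high", "p_bh",
           "tau2", "I2"]].to_string(index=False, float_format="%.3f"))

gene = top["gene_id"].iloc[0]
res = random_effects_meta(estimates[estimates["gene_id"] == gene])
print(f"\nforest table for {gene} "
      f"(true SMD {truth.config.true_smd[list(truth.gene_ids).index(gene)]:.2f}):")
print(forest_data(res).to_string(index=False, float_format="%.3f"))
print("\neach row is one study's Hedges' g with its 95% CI and")
print("random-effects weight; the summary row is the pooled estimate.")
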