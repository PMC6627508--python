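"""Why pooling samples across studies inflates false positives.

Tumor/normal labels are randomly permuted within each study, so every
"hit" is a false positive.  The pooled Welch test across all samples picks
up study batch structure and declares thousands of permuted genes
significant; the per-study + meta-analysis route stays calibrated.
"""

from metacohort import SyntheticConfig, generate_cohort, inflation_experiment

config = SyntheticConfig(n_studies=10, genes=3000, true_smd=0.0,
                         tau2_smd=0.0, batch_shift_sd=1.0, seed=41)
bundles, _ = generate_cohort(config)

report = inflation_experiment(bundles, seed=42, correction="bonferroni")
s = report.summary()
print(f"label-permuted data, {s['n_genes_pooled']} genes, "
      f"{len(bundles)} studies with batch offsets (SD 1.0):")
print(f"  pooled path : {100 * s['pooled_sig_frac']:.1f}% of genes "
      f"Bonferroni-significant, KS vs uniform = {s['pooled_ks']:.3f}")
print(f"  meta path   : {100 * s['meta_sig_frac']:.2f}% significant, "
      f"KS vs uniform = {s['meta_ks']:.3f}")
print("under a correct null both percentages should be ~0 and KS small;")
print("the pooled path's inflation is pure batch artifact.")

qq = report.qq_data()
tail = qq.groupby("path")["observed_neglog10"].max()
print(f"\nQQ tails (max observed -log10 p): "
      f"pooled {tail['pooled']:.1f} vs meta {tail['meta']:.1f}")
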