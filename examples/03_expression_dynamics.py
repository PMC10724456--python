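"""Gene-expression dynamics across gestation.

Classifies genes by Pearson correlation with gestational age (|r| > 0.7,
Bonferroni-corrected p), tests trimester pairs for > 2-fold differential
expression with BH correction, and summarizes z-score trends over five
age-ordered sample bins.
"""

from placenta_enhancers import (
    SimulationConfig,
    correlate_with_age,
    epoch_trends,
    pairwise_differential,
    simulate_dataset,
)

ds = simulate_dataset(SimulationConfig(seed=1))

age = correlate_with_age(ds.gene_expression, ds.samples, r_threshold=0.7, alpha=0.05)
counts = age["class"].value_counts()
print(f"Bonferroni cutoff: {age.attrs['bonferroni_cutoff']:.3g} "
      f"over {age.attrs['n_tested']} tested genes")
print(f"increasing with age: {counts.get('increasing', 0)}, "
      f"decreasing: {counts.get('decreasing', 0)}")

trimester = {t: ds.samples_of_trimester(t) for t in ("I", "III")}
diff = pairwise_differential(
    ds.gene_expression, trimester["I"], trimester["III"],
    fc_threshold=2.0, alpha=0.05,
)
print(f"I vs III: {int(diff['significant'].sum())} genes with >2-fold "
      "difference and q < 0.05 (positive log2FC = higher at term)")

trends = epoch_trends(ds.gene_expression, ds.samples, n_bins=5)
print("per-bin mean z of age-increasing genes should rise across bins:")
up = set(ds.truth.age_up_genes)
z = trends["zscores"].loc[sorted(up & set(trends["zscores"].index))]
for b in range(1, 6):
    cols = trends["bin_of_sample"].index[trends["bin_of_sample"] == b]
    print(f"  bin {b}: n={len(cols)} samples, mean z = "
          f"{z[cols].to_numpy().mean():+.2f}")
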