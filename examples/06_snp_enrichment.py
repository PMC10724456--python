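"""GWAS SNP density in enhancers versus genes and the genome background.

Densities are SNPs per million base pairs; the enrichment ratio divides a
region set's density by the genome-wide baseline (whole catalog over the
total genome size).
"""

import pandas as pd

from placenta_enhancers import SimulationConfig, compute_rpkm, simulate_dataset
from placenta_enhancers.snps import density_report
from placenta_enhancers.universe import build_universe, filter_distal, merge_intervals

ds = simulate_dataset(SimulationConfig(seed=1))
merged = merge_intervals(ds.tre_calls.values())
universe = build_universe(
    filter_distal(merged, ds.genes, 5000),
    compute_rpkm(
        ds.enhancer_counts,
        pd.Series({iv.id: iv.length for iv in merged}),
        ds.library_sizes,
    ),
)

gene_regions = merge_intervals([[g.interval for g in ds.genes]])
report = density_report(
    ds.snp_catalog,
    {"genes": gene_regions, "enhancers": universe.enhancers},
    ds.genome_size_bp,
)
print(report.to_string(index=False))
print(f"\nplanted enhancer SNP density ratio: "
      f"{ds.config.snp_enhancer_density_ratio}x the genome background; the "
      "estimated enhancer enrichment_ratio above should be close to it.")
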