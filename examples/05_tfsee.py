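"""TFSEE: score transcription-factor activity at enhancers per sample.

Combines min-max-normalized enhancer transcription and histone-mark
enrichment into an activity matrix, multiplies through motif predictions
and TF expression, clusters samples on 1 - Pearson distance (average
linkage), and ranks TFs by the differential score (late - early).
"""

import pandas as pd

from placenta_enhancers import SimulationConfig, compute_rpkm, simulate_dataset
from placenta_enhancers.tfsee import run_tfsee
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
uids = universe.enhancer_ids
hits = ds.motif_hits[ds.motif_hits["enhancer_id"].isin(set(uids))]

result = run_tfsee(
    universe.rpkm,
    ds.k27ac.subset_features(uids),
    ds.k4me1.subset_features(uids),
    hits,
    ds.tf_expression,
    early_samples=ds.samples_of_trimester("I", "II"),
    late_samples=ds.samples_of_trimester("III"),
    top_k=20,
)

clades = {k: sorted(v) for k, v in result.clades.items()}
print("sample dendrogram root cut:")
for k, members in clades.items():
    print(f"  clade {k}: {len(members)} samples ({members[0]}..{members[-1]})")

diff = result.differential
print("\nmost early-active TFs (delta = mean late - mean early, most negative):")
print(diff.head(3)[["tf_id", "delta_tfsee", "p_value"]].to_string(index=False))
print("\nmost term-active TFs (most positive delta):")
print(diff.tail(3)[["tf_id", "delta_tfsee", "p_value"]].to_string(index=False))
print("\nplanted early TFs:", ds.truth.early_tfs)
print("planted late TFs: ", ds.truth.late_tfs)
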