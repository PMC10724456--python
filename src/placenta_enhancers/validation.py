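"""Ground-truth recovery evaluation on synthetic studies.

Runs the actual analysis pipeline (merge -> distal filter -> RPKM
threshold -> dynamics -> TFSEE -> SNP density) on a simulated dataset and
scores every planted signal against the recorded ground truth.  Used by
the validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import correlate_with_age
from .snps import snp_density
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset, truth_report
from .tfsee import run_tfsee
from .universe import build_universe, compute_rpkm, filter_distal, merge_intervals

__all__ = ["evaluate_recovery", "recovery_study"]


def evaluate_recovery(config: SimulationConfig) -> dict:
    """Simulate one study, run the pipeline in memory, score recovery.

    Returns per-seed metrics: whether every planted TF ranks in the top 15
    by |differential TFSEE| with the correct sign, whether the root cut of
    the sample dendrogram separates trimesters I/II from III, sensitivity
    and specificity of the gestational-age gene classification, the
    enhancer-universe recovery, and the estimated enhancer SNP enrichment.
    """
    ds = simulate_dataset(config)
    truth = ds.truth

    merged = merge_intervals(ds.tre_calls.values())
    distal = filter_distal(merged, ds.genes, min_gap_bp=config.distal_min_gap_bp)
    lengths = pd.Series({iv.id: iv.length for iv in merged})
    rpkm = compute_rpkm(ds.enhancer_counts, lengths, ds.library_sizes)
    universe = build_universe(distal, rpkm, rpkm_threshold=2.0, min_samples=1)
    uids = universe.enhancer_ids

    early = ds.samples_of_trimester("I", "II")
    late = ds.samples_of_trimester("III")
    hits = ds.motif_hits[ds.motif_hits["enhancer_id"].isin(set(uids))]
    tfsee = run_tfsee(
        universe.rpkm,
        ds.k27ac.subset_features(uids),
        ds.k4me1.subset_features(uids),
        hits,
        ds.tf_expression,
        early_samples=early,
        late_samples=late,
    )
    age = correlate_with_age(ds.gene_expression, ds.samples)
    report = truth_report(
        truth,
        age_classes=age,
        differential_tfsee=tfsee.differential,
        universe_ids=uids,
        all_enhancer_ids=[iv.id for iv in merged],
    )

    ranks = report["tf_ranks"].values()
    tf_recovered = all(
        v["rank_by_abs_delta"] <= 15 and v["correct_sign"] for v in ranks
    )
    clade_sets = [set(v) for v in tfsee.clades.values()]
    clades_separate = set(early) in clade_sets and set(late) in clade_sets
    density = snp_density(ds.snp_catalog, universe.enhancers, ds.genome_size_bp)
    return {
        "tf_all_top15_correct_sign": bool(tf_recovered),
        "clades_separate_early_late": bool(clades_separate),
        "age_sensitivity": (
            report["age_up"]["sensitivity"] + report["age_down"]["sensitivity"]
        )
        / 2,
        "age_specificity": (
            report["age_up"]["specificity"] + report["age_down"]["specificity"]
        )
        / 2,
        "universe_sensitivity": report["enhancer_universe"]["sensitivity"],
        "universe_specificity": report["enhancer_universe"]["specificity"],
        "n_universe": len(uids),
        "snp_enrichment_ratio": density["enrichment_ratio"],
    }


def recovery_study(
    seeds, config_overrides: dict | None = None
) -> pd.DataFrame:
    """Evaluate recovery over a list of seeds at the default study design."""
    rows = []
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed), **(config_overrides or {}))
        row = evaluate_recovery(cfg)
        row["seed"] = int(seed)
        rows.append(row)
    return pd.DataFrame(rows)
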