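"""End-to-end orchestration: simulate -> universe -> dynamics -> link -> tfsee -> snps.

Each stage reads the files earlier stages wrote under the run directory and
writes its own subdirectory, so stages can be re-run individually.  A run
manifest records the configuration, input checksums, and per-stage status;
identical configuration + seed reproduces byte-identical outputs (the
manifest deliberately carries no wall-clock times).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as pio
from .core import AnalysisConfig, SignalMatrix
from .dynamics import correlate_with_age, epoch_trends, pairwise_differential
from .linking import enhancer_gene_correlation, enhancers_per_gene, hypergeometric_overlap, nearest_gene
from .snps import density_report
from .synthetic import SimulationConfig, simulate_dataset, write_dataset
from .tfsee import run_tfsee
from .universe import build_universe, compute_rpkm, filter_distal, merge_intervals

logger = logging.getLogger("placenta_enhancers")

ALL_STAGES = ("simulate", "universe", "dynamics", "link", "tfsee", "snps")

STAGE_REQUIRES = {
    "simulate": (),
    "universe": ("data/sample_sheet.tsv", "data/genes.bed", "data/enhancer_counts.tsv"),
    "dynamics": ("data/sample_sheet.tsv", "data/gene_expression.tsv"),
    "link": ("universe/universe.bed", "universe/universe_rpkm.tsv", "data/genes.bed"),
    "tfsee": ("universe/universe_rpkm.tsv", "data/k27ac.tsv", "data/motif_hits.tsv"),
    "snps": ("universe/universe.bed", "data/snp_catalog.tsv", "data/genes.bed"),
}


class StageInputError(RuntimeError):
    """A requested stage is missing an upstream output."""


def _check_inputs(outdir: Path, stage: str) -> None:
    missing = [f for f in STAGE_REQUIRES[stage] if not (outdir / f).exists()]
    if missing:
        upstream = "simulate" if missing[0].startswith("data/") else "universe"
        raise StageInputError(
            f"stage {stage!r} is missing inputs {missing}; run stage "
            f"{upstream!r} first"
        )


def _stage_simulate(outdir: Path, sim_config: SimulationConfig, _: AnalysisConfig):
    ds = simulate_dataset(sim_config)
    return write_dataset(ds, outdir / "data")


def _read_common(outdir: Path):
    samples = pio.read_sample_sheet(outdir / "data" / "sample_sheet.tsv")
    sample_ids = [s.sample_id for s in samples]
    return samples, sample_ids


def _stage_universe(outdir: Path, _: SimulationConfig, cfg: AnalysisConfig):
    samples, sample_ids = _read_common(outdir)
    genes = pio.read_gene_annotation(outdir / "data" / "genes.bed")
    tre_sets = [
        pio.read_intervals(outdir / "data" / "tre" / f"{sid}.bed")
        for sid in sample_ids
    ]
    merged = merge_intervals(tre_sets)
    distal = filter_distal(merged, genes, min_gap_bp=cfg.distal_min_gap_bp)
    counts = pio.read_matrix(
        outdir / "data" / "enhancer_counts.tsv", "counts"
    ).reindex_samples(sample_ids)
    libsizes = pd.read_csv(
        outdir / "data" / "library_sizes.tsv", sep="\t"
    ).set_index("sample_id")["library_size"]
    lengths = pd.Series({iv.id: iv.length for iv in merged})
    rpkm = compute_rpkm(counts, lengths, libsizes)
    uni = build_universe(
        distal,
        rpkm,
        rpkm_threshold=cfg.rpkm_threshold,
        min_samples=cfg.min_samples,
        provenance={
            "min_gap_bp": cfg.distal_min_gap_bp,
            "n_merged_tres": len(merged),
            "n_distal_tres": len(distal),
        },
    )
    udir = outdir / "universe"
    udir.mkdir(parents=True, exist_ok=True)
    pio.write_intervals(uni.enhancers, udir / "universe.bed")
    pio.write_matrix(uni.rpkm, udir / "universe_rpkm.tsv")
    merged_ids = sorted(iv.id for iv in merged)
    pio.write_json(
        {"provenance": uni.provenance, "merged_tre_ids": merged_ids},
        udir / "provenance.json",
    )
    return uni.provenance


def _trimester_groups(samples):
    groups = {"I": [], "II": [], "III": []}
    for s in samples:
        groups[s.trimester].append(s.sample_id)
    return groups


def _stage_dynamics(outdir: Path, _: SimulationConfig, cfg: AnalysisConfig):
    samples, sample_ids = _read_common(outdir)
    expr = pio.read_matrix(
        outdir / "data" / "gene_expression.tsv", "normalized"
    ).reindex_samples(sample_ids)
    ddir = outdir / "dynamics"
    ddir.mkdir(parents=True, exist_ok=True)
    age = correlate_with_age(
        expr, samples, r_threshold=cfg.pearson_r_threshold, alpha=cfg.alpha
    )
    pio.write_table(age, ddir / "age_correlation.tsv")
    groups = _trimester_groups(samples)
    for a, b in (("I", "II"), ("I", "III"), ("II", "III")):
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            table = pairwise_differential(
                expr,
                groups[a],
                groups[b],
                fc_threshold=cfg.fold_change_threshold,
                alpha=cfg.alpha,
                pseudocount=cfg.pseudocount,
            )
            pio.write_table(table, ddir / f"differential_{a}_vs_{b}.tsv")
    trends = epoch_trends(expr, samples, n_bins=cfg.n_epoch_bins)
    pio.write_table(trends["bin_summary"], ddir / "epoch_trends.tsv")
    return {
        "n_increasing": int((age["class"] == "increasing").sum()),
        "n_decreasing": int((age["class"] == "decreasing").sum()),
    }


def _stage_link(outdir: Path, _: SimulationConfig, cfg: AnalysisConfig):
    samples, sample_ids = _read_common(outdir)
    genes = pio.read_gene_annotation(outdir / "data" / "genes.bed")
    universe = pio.read_intervals(outdir / "universe" / "universe.bed")
    rpkm = pio.read_matrix(
        outdir / "universe" / "universe_rpkm.tsv", "RPKM"
    ).reindex_samples(sample_ids)
    expr = pio.read_matrix(
        outdir / "data" / "gene_expression.tsv", "normalized"
    ).reindex_samples(sample_ids)
    ldir = outdir / "link"
    ldir.mkdir(parents=True, exist_ok=True)
    links = nearest_gene(universe, genes)
    pio.write_table(links, ldir / "links.tsv")
    pio.write_table(enhancers_per_gene(links), ldir / "enhancers_per_gene.tsv")
    corr = enhancer_gene_correlation(rpkm, expr, links)
    pio.write_table(corr, ldir / "enh_gene_correlation.tsv")
    # overlap of enhancer-linked genes with gestational-age-correlated genes
    age_path = outdir / "dynamics" / "age_correlation.tsv"
    overlaps = []
    if age_path.exists():
        age = pd.read_csv(age_path, sep="\t")
        linked_genes = set(links.loc[links["linked"].astype(bool), "gene_id"])
        for cls in ("increasing", "decreasing"):
            genes_cls = set(age.loc[age["class"] == cls, "gene_id"])
            res = hypergeometric_overlap(linked_genes, genes_cls, len(genes))
            res["comparison"] = f"linked_vs_{cls}"
            overlaps.append(res)
    if overlaps:
        pio.write_table(pd.DataFrame(overlaps), ldir / "overlap_tests.tsv")
    return {"n_links": int(links["linked"].astype(bool).sum())}


def _stage_tfsee(outdir: Path, _: SimulationConfig, cfg: AnalysisConfig):
    samples, sample_ids = _read_common(outdir)
    rpkm = pio.read_matrix(
        outdir / "universe" / "universe_rpkm.tsv", "RPKM"
    ).reindex_samples(sample_ids)
    universe_ids = rpkm.feature_ids
    k27 = (
        pio.read_matrix(outdir / "data" / "k27ac.tsv", "counts")
        .subset_features(universe_ids)
        .reindex_samples(sample_ids)
    )
    k4 = (
        pio.read_matrix(outdir / "data" / "k4me1.tsv", "counts")
        .subset_features(universe_ids)
        .reindex_samples(sample_ids)
    )
    tf_expr = pio.read_matrix(
        outdir / "data" / "tf_expression.tsv", "normalized"
    ).reindex_samples(sample_ids)
    hits = pd.read_csv(outdir / "data" / "motif_hits.tsv", sep="\t")
    hits = hits[hits["enhancer_id"].isin(set(universe_ids))]
    groups = _trimester_groups(samples)
    result = run_tfsee(
        rpkm,
        k27,
        k4,
        hits,
        tf_expr,
        early_samples=groups["I"] + groups["II"],
        late_samples=groups["III"],
        top_k=cfg.tfsee_top_k_motifs,
        alpha=cfg.alpha,
    )
    tdir = outdir / "tfsee"
    tdir.mkdir(parents=True, exist_ok=True)
    pio.write_matrix(SignalMatrix(result.scores.T, "normalized"), tdir / "tfsee_scores.tsv")
    pio.write_json(
        {
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h), "size": int(n)}
                for a, b, h, n in result.linkage
            ],
            "leaf_order": result.leaf_order,
            "clades": {str(k): v for k, v in result.clades.items()},
        },
        tdir / "linkage.json",
    )
    pio.write_table(result.differential, tdir / "differential_tfsee.tsv")
    return {"n_significant_tfs": int(result.differential["significant"].sum())}


def _stage_snps(outdir: Path, _: SimulationConfig, cfg: AnalysisConfig):
    import json

    genes = pio.read_gene_annotation(outdir / "data" / "genes.bed")
    universe = pio.read_intervals(outdir / "universe" / "universe.bed")
    catalog = pio.read_snp_catalog(outdir / "data" / "snp_catalog.tsv")
    sim_cfg = json.loads((outdir / "data" / "simulation_config.json").read_text())[
        "simulation_config"
    ]
    genome = sim_cfg["n_chromosomes"] * sim_cfg["chrom_length_bp"]
    gene_ivs = merge_intervals([[g.interval for g in genes]])
    report = density_report(
        catalog, {"genes": gene_ivs, "enhancers": universe}, genome
    )
    sdir = outdir / "snps"
    sdir.mkdir(parents=True, exist_ok=True)
    pio.write_table(report, sdir / "snp_density.tsv")
    return {
        "enhancer_enrichment_ratio": float(
            report.loc[report["region_set"] == "enhancers", "enrichment_ratio"].iloc[0]
        )
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "universe": _stage_universe,
    "dynamics": _stage_dynamics,
    "link": _stage_link,
    "tfsee": _stage_tfsee,
    "snps": _stage_snps,
}


def run_pipeline(
    outdir: str | Path,
    sim_config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    A failure in stage k leaves earlier stages' outputs intact and marks
    the manifest ``failed`` at that stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or SimulationConfig()
    analysis_config = analysis_config or AnalysisConfig()
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {ALL_STAGES}")
    ordered = [s for s in ALL_STAGES if s in stages]
    manifest: dict = {
        "simulation_config": asdict(sim_config),
        "analysis_config": asdict(analysis_config),
        "seed": sim_config.seed,
        "stages": {},
    }
    for stage in ordered:
        t0 = time.monotonic()
        logger.info("stage %s: starting", stage)
        try:
            _check_inputs(outdir, stage)
            summary = _STAGE_FUNCS[stage](outdir, sim_config, analysis_config)
            manifest["stages"][stage] = {"status": "completed", "summary": summary}
            logger.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)
        except Exception as exc:
            manifest["stages"][stage] = {"status": f"failed: {exc}"}
            pio.write_json(manifest, outdir / "manifest.json")
            logger.error(
                "stage %s: failed after %.1fs: %s", stage, time.monotonic() - t0, exc
            )
            raise
    data_dir = outdir / "data"
    if data_dir.exists():
        manifest["input_checksums"] = {
            str(p.relative_to(outdir)): pio.file_sha256(p)
            for p in sorted(data_dir.rglob("*"))
            if p.is_file()
        }
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
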