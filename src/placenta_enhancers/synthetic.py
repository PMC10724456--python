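"""Synthetic multi-omic placental study generator with recorded ground truth.

Emulates the structure of the real study: 36 placental samples (12 per
trimester) with nascent transcription (eRNA/PRO-seq-like), H3K27ac and
H3K4me1 ChIP enrichment, RNA-seq gene and TF expression, per-sample TRE
interval calls, motif hits linking enhancers to TFs, and a GWAS-style SNP
catalog with elevated density inside enhancers.

The genome is laid out in blocks, one gene per block, with a candidate
enhancer placed mid-block strictly more than the distal gap from every
gene span.  Per-sample TRE calls contain the active planted enhancers plus
random promoter-proximal decoy intervals (within 5 kb of a gene) that the
distal filter must remove.  All sequencing-derived counts are negative
binomial (mean-dispersion parameterization); histone marks are monotone
noisy transforms of the eRNA means; TF expression and motif content carry
planted "early" (trimester I/II) and "late" (trimester III) programs; a
fraction of genes is linear in gestational age.  One root seed drives
every stochastic routine through deterministically spawned child streams,
so identical configurations reproduce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .core import GeneModel, GenomicInterval, SampleRecord, SignalMatrix
from .universe import merge_intervals

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "write_dataset",
    "load_dataset",
    "confusion_metrics",
    "truth_report",
]

GWAS_TRAITS = (
    "preeclampsia",
    "gestational_hypertension",
    "birth_weight",
    "gestational_diabetes",
    "preterm_birth",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the study conditions used throughout the test
    suite: 36 samples (12 per trimester), 500 candidate enhancers over
    2000 genes, 5 early + 5 late + 50 decoy TFs, and a 2-log2 (4-fold)
    planted activity difference between early and late programs.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 12_000_000
    n_genes: int = 2000
    n_enhancers: int = 500
    n_samples_per_trimester: int = 12
    n_tfs_early: int = 5
    n_tfs_late: int = 5
    n_tfs_decoy: int = 50
    effect_size_log2: float = 2.0
    nb_dispersion: float = 0.1
    frac_age_correlated_genes: float = 0.2
    snp_enhancer_density_ratio: float = 3.0
    n_snps: int = 20_000
    seed: int = 0
    # geometry (bp)
    gene_length_bp: int = 2000
    enhancer_length_bp: int = 350
    distal_min_gap_bp: int = 5000
    # sequencing scale
    library_size_mean: float = 2.0e7
    n_decoy_tres_per_sample: int = 40

    def __post_init__(self):
        if self.n_enhancers > self.n_genes:
            raise ValueError("layout requires n_enhancers <= n_genes")
        if not 0 <= self.frac_age_correlated_genes <= 1:
            raise ValueError("frac_age_correlated_genes must be in [0, 1]")
        for name in ("nb_dispersion", "snp_enhancer_density_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery scoring."""

    early_tfs: list[str]
    late_tfs: list[str]
    decoy_tfs: list[str]
    enhancer_program: dict  # enhancer_id -> {class, tfs, target_gene}
    age_up_genes: list[str]
    age_down_genes: list[str]
    planted_snp_counts: dict  # {"inside_enhancers": n, "outside_enhancers": n}

    def __post_init__(self):
        sets = [set(self.early_tfs), set(self.late_tfs), set(self.decoy_tfs)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("TF ground-truth classes must be disjoint")
        classes = {p["class"] for p in self.enhancer_program.values()}
        for cls in ("early", "late", "constitutive"):
            if cls not in classes:
                raise ValueError(f"no planted enhancer of class {cls!r}")

    def enhancers_of_class(self, cls: str) -> list[str]:
        return [e for e, p in self.enhancer_program.items() if p["class"] == cls]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    samples: list[SampleRecord]
    tre_calls: dict  # sample_id -> list[GenomicInterval]
    library_sizes: pd.Series
    enhancer_counts: SignalMatrix  # merged TRE union x samples (eRNA counts)
    k27ac: SignalMatrix
    k4me1: SignalMatrix
    gene_expression: SignalMatrix  # FPKM-like, genes x samples
    tf_expression: SignalMatrix  # TFs x samples
    motif_hits: pd.DataFrame
    snp_catalog: pd.DataFrame
    truth: GroundTruth

    @property
    def enhancer_lengths(self) -> pd.Series:
        lengths = {}
        for fid in self.enhancer_counts.feature_ids:
            span = fid.split(":")[1]
            start, end = span.split("-")
            lengths[fid] = int(end) - int(start)
        return pd.Series(lengths)

    @property
    def genome_size_bp(self) -> int:
        return self.config.n_chromosomes * self.config.chrom_length_bp

    def samples_of_trimester(self, *trimesters: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.trimester in trimesters]


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam).astype(float)


def _layout(config: SimulationConfig, rng: np.random.Generator):
    """Place one gene per block and enhancers in evenly spread blocks.

    Raises before anything else is generated when the genome cannot hold
    the requested genes/enhancers with the required distal gaps.
    """
    blocks_per_chrom = -(-config.n_genes // config.n_chromosomes)
    block = config.chrom_length_bp // blocks_per_chrom
    jitter_max = 200
    need = (
        config.gene_length_bp
        + 2 * (config.distal_min_gap_bp + 1)
        + config.enhancer_length_bp
        + jitter_max
        + 500
    )
    if block < need:
        raise ValueError(
            f"genome too small: block span {block} bp < required {need} bp "
            f"for {config.n_genes} genes with {config.distal_min_gap_bp} bp gaps"
        )
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        x = (i // config.n_chromosomes) * block
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                GenomicInterval(
                    chrom,
                    x,
                    x + config.gene_length_bp,
                    strand=strand,
                    id=f"gene{i:04d}",
                )
            )
        )
    enhancer_blocks = [
        round(i * config.n_genes / config.n_enhancers)
        for i in range(config.n_enhancers)
    ]
    enhancers: list[GenomicInterval] = []
    host_gene: list[str] = []
    for b in enhancer_blocks:
        g = genes[b].interval
        jit = int(rng.integers(0, jitter_max))
        start = g.end + config.distal_min_gap_bp + 501 + jit
        enhancers.append(
            GenomicInterval(g.chrom, start, start + config.enhancer_length_bp)
        )
        host_gene.append(genes[b].gene_id)
    return genes, enhancers, host_gene


def _make_samples(config: SimulationConfig, rng: np.random.Generator):
    """12 samples per trimester: ages uniform in 6-13 wk (I) and 14-27 wk
    (II), and a term cluster fixed at 39 wk (III)."""
    samples = []
    idx = 1
    for trimester, (lo, hi) in (("I", (6.0, 13.0)), ("II", (14.0, 27.0))):
        for _ in range(config.n_samples_per_trimester):
            age = round(float(rng.uniform(lo, hi)), 1)
            samples.append(
                SampleRecord(
                    sample_id=f"P{idx:02d}",
                    gestational_age_weeks=age,
                    trimester=trimester,
                    sex="F" if rng.random() < 0.5 else "M",
                )
            )
            idx += 1
    for _ in range(config.n_samples_per_trimester):
        samples.append(
            SampleRecord(
                sample_id=f"P{idx:02d}",
                gestational_age_weeks=39.0,
                trimester="III",
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
        idx += 1
    return samples


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study in memory.

    Deterministic in ``config`` (including ``config.seed``): every
    stochastic routine uses its own child stream spawned, in fixed order,
    from one root :class:`numpy.random.SeedSequence`.
    """
    root = np.random.SeedSequence(config.seed)
    (
        ss_layout,
        ss_samples,
        ss_erna,
        ss_marks,
        ss_genes,
        ss_tfs,
        ss_motifs,
        ss_snps,
        ss_tres,
    ) = [np.random.default_rng(s) for s in root.spawn(9)]

    genes, enhancers, host_gene = _layout(config, ss_layout)
    samples = _make_samples(config, ss_samples)
    sample_ids = [s.sample_id for s in samples]
    trimesters = np.array([s.trimester for s in samples])
    ages = np.array([s.gestational_age_weeks for s in samples])
    early_mask = np.isin(trimesters, ["I", "II"])
    late_mask = trimesters == "III"

    # --- enhancer classes: planted early/late programs + constitutive
    n_e = config.n_enhancers
    classes = np.array(["constitutive"] * n_e, dtype=object)
    n_early = max(1, int(round(n_e * 0.3)))
    n_late = max(1, int(round(n_e * 0.3)))
    order = ss_layout.permutation(n_e)
    classes[order[:n_early]] = "early"
    classes[order[n_early : n_early + n_late]] = "late"

    # --- TF universe
    early_tfs = [f"TF_early{i + 1:02d}" for i in range(config.n_tfs_early)]
    late_tfs = [f"TF_late{i + 1:02d}" for i in range(config.n_tfs_late)]
    decoy_tfs = [f"TF_decoy{i + 1:02d}" for i in range(config.n_tfs_decoy)]
    tf_ids = early_tfs + late_tfs + decoy_tfs

    # --- library sizes
    libsizes = pd.Series(
        config.library_size_mean * np.exp(ss_erna.normal(0, 0.15, len(sample_ids))),
        index=sample_ids,
        name="library_size",
    ).round()

    # --- per-sample TRE calls: active planted enhancers + promoter-proximal decoys
    tre_calls: dict[str, list[GenomicInterval]] = {}
    for s in samples:
        active = []
        for enh, cls in zip(enhancers, classes):
            if (
                cls == "constitutive"
                or (cls == "early" and s.trimester in ("I", "II"))
                or (cls == "late" and s.trimester == "III")
            ):
                active.append(GenomicInterval(enh.chrom, enh.start, enh.end))
        for _ in range(config.n_decoy_tres_per_sample):
            g = genes[int(ss_tres.integers(0, len(genes)))].interval
            length = int(ss_tres.integers(250, 401))
            lo = max(0, g.start - config.distal_min_gap_bp)
            hi = g.end + config.distal_min_gap_bp - length
            start = int(ss_tres.integers(lo, hi + 1))
            active.append(GenomicInterval(g.chrom, start, start + length))
        active.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        tre_calls[s.sample_id] = active

    # --- merged TRE union defines the count-matrix features
    union = merge_intervals(tre_calls.values())
    union_ids = [iv.id for iv in union]
    planted_ids = {iv.id for iv in enhancers}
    planted_class = {iv.id: cls for iv, cls in zip(enhancers, classes)}

    # --- eRNA counts: NB around class- and trimester-dependent means
    fold = 2.0**config.effect_size_log2
    depth = (libsizes / config.library_size_mean).to_numpy()
    base_low: dict[str, float] = {}
    mean_rows = []
    for iv in union:
        if iv.id in planted_ids:
            base = float(2.0 ** ss_erna.uniform(4.0, 6.0))
            cls = planted_class[iv.id]
            mult = np.ones(len(sample_ids))
            if cls == "early":
                mult[early_mask] = fold
            elif cls == "late":
                mult[late_mask] = fold
            else:
                base *= 2.0
            mean_rows.append(base * mult * depth)
            base_low[iv.id] = base
        else:  # merged decoy TREs: promoter-proximal background transcription
            base = float(ss_erna.uniform(0.5, 2.0))
            mean_rows.append(base * np.ones(len(sample_ids)) * depth)
            base_low[iv.id] = base
    mean_matrix = np.vstack(mean_rows)
    erna_counts = _nb_draw(ss_erna, mean_matrix, config.nb_dispersion)
    enhancer_counts = SignalMatrix(
        pd.DataFrame(erna_counts, index=union_ids, columns=sample_ids), "counts"
    )

    # --- histone marks: monotone noisy transforms of the eRNA means
    k27_mean = 4.0 * mean_matrix
    k4_mean = 40.0 * np.sqrt(mean_matrix)
    k27ac = SignalMatrix(
        pd.DataFrame(
            _nb_draw(ss_marks, k27_mean, config.nb_dispersion),
            index=union_ids,
            columns=sample_ids,
        ),
        "counts",
    )
    k4me1 = SignalMatrix(
        pd.DataFrame(
            _nb_draw(ss_marks, k4_mean, config.nb_dispersion),
            index=union_ids,
            columns=sample_ids,
        ),
        "counts",
    )

    # --- gene expression (FPKM-like): enhancer-coupled, age-linear, or flat
    coupled: dict[str, str] = {}  # gene_id -> enhancer class driving it
    for enh, cls, host in zip(enhancers, classes, host_gene):
        if cls in ("early", "late"):
            coupled[host] = cls
    n_corr = int(round(config.frac_age_correlated_genes * config.n_genes))
    free = [g.gene_id for g in genes if g.gene_id not in coupled]
    picked = list(ss_genes.permutation(np.array(free))[:n_corr])
    linear_up = sorted(picked[: n_corr // 2])
    linear_down = sorted(picked[n_corr // 2 :])
    up_set, down_set = set(linear_up), set(linear_down)
    expr_rows = []
    for g in genes:
        gid = g.gene_id
        if gid in coupled:
            mult = np.ones(len(sample_ids))
            if coupled[gid] == "early":
                mult[early_mask] = fold
            else:
                mult[late_mask] = fold
            mean = 20.0 * mult
            expr = np.maximum(
                0.01, ss_genes.normal(mean, 0.15 * mean + 2.0)
            )
        elif gid in up_set or gid in down_set:
            slope = float(ss_genes.uniform(0.8, 1.2))
            if gid in down_set:
                slope = -slope
            expr = np.maximum(
                0.01, 50.0 + slope * (ages - ages.mean()) + ss_genes.normal(0, 7.0, len(ages))
            )
        else:
            base = float(2.0 ** ss_genes.uniform(2.0, 7.0))
            expr = np.maximum(
                0.01, ss_genes.normal(base, 0.2 * base + 1.0, len(ages))
            )
        expr_rows.append(expr)
    gene_expression = SignalMatrix(
        pd.DataFrame(
            np.vstack(expr_rows),
            index=[g.gene_id for g in genes],
            columns=sample_ids,
        ),
        "normalized",
    )
    age_down_genes = sorted(
        set(linear_down) | {g for g, c in coupled.items() if c == "early"}
    )
    age_up_genes = sorted(
        set(linear_up) | {g for g, c in coupled.items() if c == "late"}
    )

    # --- TF expression: early TFs elevated in trimester I/II, late in III
    tf_rows = []
    for tf in tf_ids:
        mult = np.ones(len(sample_ids))
        if tf in early_tfs:
            mult[early_mask] = fold
        elif tf in late_tfs:
            mult[late_mask] = fold
        mean = 25.0 * mult
        tf_rows.append(np.maximum(0.01, ss_tfs.normal(mean, 0.15 * mean + 1.0)))
    tf_expression = SignalMatrix(
        pd.DataFrame(np.vstack(tf_rows), index=tf_ids, columns=sample_ids),
        "normalized",
    )

    # --- motif hits: planted program motifs (strong) + decoy background
    hit_rows = []
    program: dict[str, dict] = {}
    motif_counter = 0
    for enh, cls, host in zip(enhancers, classes, host_gene):
        carried = []
        planted_pool = (
            early_tfs if cls == "early" else late_tfs if cls == "late" else []
        )
        for tf in planted_pool:
            if ss_motifs.random() < 0.8:
                carried.append(tf)
                p = 10.0 ** ss_motifs.uniform(-12.0, -6.0)
                hit_rows.append((enh.id, tf, f"m{motif_counter:06d}", p))
                motif_counter += 1
        n_bg = int(ss_motifs.poisson(10))
        for tf in ss_motifs.choice(np.array(decoy_tfs), size=n_bg, replace=True):
            p = 10.0 ** ss_motifs.uniform(-4.0, -2.0)
            hit_rows.append((enh.id, str(tf), f"m{motif_counter:06d}", p))
            motif_counter += 1
        program[enh.id] = {"class": cls, "tfs": carried, "target_gene": host}
    motif_hits = pd.DataFrame(
        hit_rows, columns=["enhancer_id", "tf_id", "motif_id", "match_p"]
    )

    # --- SNP catalog: uniform background + surplus inside enhancers
    genome = config.n_chromosomes * config.chrom_length_bp
    pos = ss_snps.integers(0, config.chrom_length_bp, config.n_snps)
    chrom_idx = ss_snps.integers(0, config.n_chromosomes, config.n_snps)
    snp_chroms = [f"chr{c + 1}" for c in chrom_idx]
    snp_pos = list(pos)
    enh_bp = sum(iv.length for iv in enhancers)
    bg_rate = config.n_snps / genome
    extra = ss_snps.poisson(
        (config.snp_enhancer_density_ratio - 1.0) * bg_rate * enh_bp
    )
    enh_starts = np.array([iv.start for iv in enhancers])
    enh_lens = np.array([iv.length for iv in enhancers])
    for _ in range(int(extra)):
        j = int(ss_snps.integers(0, len(enhancers)))
        snp_chroms.append(enhancers[j].chrom)
        snp_pos.append(int(enh_starts[j] + ss_snps.integers(0, enh_lens[j])))
    traits = ss_snps.choice(np.array(GWAS_TRAITS), size=len(snp_pos), replace=True)
    snp_catalog = pd.DataFrame(
        {
            "snp_id": [f"rs{i:07d}" for i in range(len(snp_pos))],
            "chrom": snp_chroms,
            "pos": snp_pos,
            "trait": traits,
        }
    )
    by_chrom = {}
    for iv in enhancers:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    inside = 0
    for chrom, p in zip(snp_catalog["chrom"], snp_catalog["pos"]):
        spans = by_chrom.get(chrom, [])
        if any(s <= p < e for s, e in spans):
            inside += 1

    truth = GroundTruth(
        early_tfs=early_tfs,
        late_tfs=late_tfs,
        decoy_tfs=decoy_tfs,
        enhancer_program=program,
        age_up_genes=age_up_genes,
        age_down_genes=age_down_genes,
        planted_snp_counts={
            "inside_enhancers": inside,
            "outside_enhancers": len(snp_pos) - inside,
        },
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        samples=samples,
        tre_calls=tre_calls,
        library_sizes=libsizes,
        enhancer_counts=enhancer_counts,
        k27ac=k27ac,
        k4me1=k4me1,
        gene_expression=gene_expression,
        tf_expression=tf_expression,
        motif_hits=motif_hits,
        snp_catalog=snp_catalog,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict:
    """Write every emitted file in the formats the pipeline reads.

    Returns a manifest of relative path -> SHA-256.
    """
    outdir = Path(outdir)
    (outdir / "tre").mkdir(parents=True, exist_ok=True)
    pio.write_intervals([g.interval for g in ds.genes], outdir / "genes.bed")
    pio.write_sample_sheet(ds.samples, outdir / "sample_sheet.tsv")
    for sid, ivs in ds.tre_calls.items():
        pio.write_intervals(ivs, outdir / "tre" / f"{sid}.bed")
    ds.library_sizes.to_frame().reset_index(names="sample_id").to_csv(
        outdir / "library_sizes.tsv", sep="\t", index=False, float_format="%.0f"
    )
    pio.write_matrix(ds.enhancer_counts, outdir / "enhancer_counts.tsv")
    pio.write_matrix(ds.k27ac, outdir / "k27ac.tsv")
    pio.write_matrix(ds.k4me1, outdir / "k4me1.tsv")
    pio.write_matrix(ds.gene_expression, outdir / "gene_expression.tsv")
    pio.write_matrix(ds.tf_expression, outdir / "tf_expression.tsv")
    ds.motif_hits.to_csv(
        outdir / "motif_hits.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pio.write_snp_catalog(ds.snp_catalog, outdir / "snp_catalog.tsv")
    pio.write_json(ds.truth.to_dict(), outdir / "ground_truth.json")
    pio.write_json(
        {"simulation_config": asdict(ds.config)}, outdir / "simulation_config.json"
    )
    files = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
    )
    return {f: pio.file_sha256(outdir / f) for f in files}


def load_dataset(outdir: str | Path) -> dict:
    """Reload the emitted files through the standard readers."""
    outdir = Path(outdir)
    samples = pio.read_sample_sheet(outdir / "sample_sheet.tsv")
    libsizes = pd.read_csv(outdir / "library_sizes.tsv", sep="\t").set_index(
        "sample_id"
    )["library_size"]
    return {
        "genes": pio.read_gene_annotation(outdir / "genes.bed"),
        "samples": samples,
        "tre_calls": {
            s.sample_id: pio.read_intervals(outdir / "tre" / f"{s.sample_id}.bed")
            for s in samples
        },
        "library_sizes": libsizes,
        "enhancer_counts": pio.read_matrix(outdir / "enhancer_counts.tsv", "counts"),
        "k27ac": pio.read_matrix(outdir / "k27ac.tsv", "counts"),
        "k4me1": pio.read_matrix(outdir / "k4me1.tsv", "counts"),
        "gene_expression": pio.read_matrix(
            outdir / "gene_expression.tsv", "normalized"
        ),
        "tf_expression": pio.read_matrix(outdir / "tf_expression.tsv", "normalized"),
        "motif_hits": pd.read_csv(outdir / "motif_hits.tsv", sep="\t"),
        "snp_catalog": pio.read_snp_catalog(outdir / "snp_catalog.tsv"),
    }


def confusion_metrics(predicted, truth, universe) -> dict:
    """Sensitivity/specificity of a predicted id set against a planted set."""
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    stray = (predicted | truth) - universe
    if stray:
        raise ValueError(f"ids outside the shared universe: {sorted(stray)[:5]}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(truth) if truth else 1.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
    }


def truth_report(
    truth: GroundTruth,
    age_classes: pd.DataFrame | None = None,
    differential_tfsee: pd.DataFrame | None = None,
    universe_ids: list | None = None,
    all_enhancer_ids: list | None = None,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    ``age_classes`` is a table from the age-correlation classifier,
    ``differential_tfsee`` a ranked TF table, ``universe_ids`` the final
    enhancer universe (scored against all merged TRE ids in
    ``all_enhancer_ids``).  Metrics lie in [0, 1]; planted-TF rank
    positions are 1-based within the differential ordering.
    """
    report: dict = {}
    if age_classes is not None:
        genes = list(age_classes["gene_id"])
        up_pred = set(age_classes.loc[age_classes["class"] == "increasing", "gene_id"])
        down_pred = set(
            age_classes.loc[age_classes["class"] == "decreasing", "gene_id"]
        )
        missing = (set(truth.age_up_genes) | set(truth.age_down_genes)) - set(genes)
        if missing:
            raise ValueError(f"planted genes missing from results: {sorted(missing)[:5]}")
        report["age_up"] = confusion_metrics(up_pred, truth.age_up_genes, genes)
        report["age_down"] = confusion_metrics(down_pred, truth.age_down_genes, genes)
    if differential_tfsee is not None:
        table = differential_tfsee.reset_index(drop=True)
        pos_by_abs = (
            table.reindex(
                table["delta_tfsee"].abs().sort_values(ascending=False, kind="stable").index
            )
            .reset_index(drop=True)
        )
        abs_rank = {tf: i + 1 for i, tf in enumerate(pos_by_abs["tf_id"])}
        planted = truth.early_tfs + truth.late_tfs
        missing = [tf for tf in planted if tf not in abs_rank]
        if missing:
            raise ValueError(f"planted TFs missing from differential table: {missing}")
        delta = dict(zip(table["tf_id"], table["delta_tfsee"]))
        report["tf_ranks"] = {
            tf: {
                "rank_by_abs_delta": abs_rank[tf],
                "delta": float(delta[tf]),
                "correct_sign": bool(
                    delta[tf] < 0 if tf in truth.early_tfs else delta[tf] > 0
                ),
            }
            for tf in planted
        }
    if universe_ids is not None:
        if all_enhancer_ids is None:
            raise ValueError("universe scoring needs all_enhancer_ids")
        planted_distal = list(truth.enhancer_program)
        report["enhancer_universe"] = confusion_metrics(
            universe_ids, planted_distal, all_enhancer_ids
        )
    return report
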