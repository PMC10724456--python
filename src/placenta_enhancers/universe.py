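"""Expressed distal enhancer universe construction.

Per-sample transcribed-regulatory-element (TRE) calls are merged into a
non-redundant union, promoter/gene-proximal elements are removed with a
distal filter (> ``min_gap_bp`` from any gene span by default), element
transcription is quantified as RPKM, and weakly transcribed elements are
dropped (RPKM >= threshold in at least ``min_samples`` samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    SignalMatrix,
    check_shared_chromosomes,
    interval_gap,
)

__all__ = [
    "EnhancerUniverse",
    "merge_intervals",
    "filter_distal",
    "compute_rpkm",
    "build_universe",
    "region_overlap_summary",
]


@dataclass
class EnhancerUniverse:
    """Filtered merged enhancers plus their RPKM matrix and filter provenance."""

    enhancers: list[GenomicInterval]
    rpkm: SignalMatrix
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.id for e in self.enhancers]
        if ids != self.rpkm.feature_ids:
            raise ValueError("enhancer order does not match RPKM feature order")
        for prev, cur in zip(self.enhancers, self.enhancers[1:]):
            if (cur.chrom, cur.start) < (prev.chrom, prev.start):
                raise ValueError("enhancers not sorted by (chrom, start)")
            if prev.overlaps(cur):
                raise ValueError(f"overlapping enhancers {prev.id} / {cur.id}")

    @property
    def enhancer_ids(self) -> list[str]:
        return [e.id for e in self.enhancers]

    def __len__(self) -> int:
        return len(self.enhancers)


def merge_intervals(
    interval_sets: Iterable[Iterable[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union of per-sample interval calls into non-overlapping sorted runs.

    Overlapping and bookended (gap 0) intervals merge; a 1-bp gap keeps two
    runs separate.  Output ids are content-addressed as ``chrom:start-end``,
    strand is dropped (merged TREs are unstranded).
    """
    flat = [iv for ivs in interval_sets for iv in ivs]
    flat.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv in flat:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
            continue
        if cur_chrom is not None:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
        cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def filter_distal(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    min_gap_bp: int = 5000,
    mode: str = "span",
) -> list[GenomicInterval]:
    """Retain enhancers whose gap to every gene strictly exceeds ``min_gap_bp``.

    ``mode='span'`` measures the gap to the whole gene body (its 5' and 3'
    ends); ``mode='tss'`` measures it to the TSS position only.  Retention
    is strand-agnostic.  An empty gene set is an error: the filter would be
    vacuous.
    """
    if not genes:
        raise ValueError("empty gene set: distal filter would be vacuous")
    if mode not in ("span", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_ivs = [g.interval for g in genes]
    if mode == "tss":
        gene_ivs = [
            GenomicInterval(g.interval.chrom, g.tss, g.tss + 1, id=g.gene_id)
            for g in genes
        ]
    check_shared_chromosomes(enhancers, gene_ivs, "enhancer", "gene")

    # per-chromosome sorted edge arrays; nearest gap via binary search
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in gene_ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts_ends = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        ends = np.maximum.accumulate(np.array([e for _, e in spans]))
        starts_ends[chrom] = (starts, ends)

    kept = []
    for enh in enhancers:
        se = starts_ends.get(enh.chrom)
        if se is None:
            kept.append(enh)
            continue
        starts, ends = se
        # genes starting at/after the enhancer end vs all genes starting before
        i = int(np.searchsorted(starts, enh.end))
        gap_right = starts[i] - enh.end if i < len(starts) else None
        gap_left = enh.start - ends[i - 1] if i > 0 else None
        min_gap = min(
            (max(0, g) for g in (gap_right, gap_left) if g is not None),
            default=None,
        )
        if min_gap is None or min_gap > min_gap_bp:
            kept.append(enh)
    return kept


def compute_rpkm(
    counts: SignalMatrix,
    lengths: pd.Series | dict,
    library_sizes: pd.Series | dict,
) -> SignalMatrix:
    """Reads per kilobase of feature per million mapped reads.

    RPKM(f, s) = counts(f, s) / ((length_f / 1e3) * (library_size_s / 1e6)).
    """
    lengths = pd.Series(lengths, dtype=float).reindex(counts.feature_ids)
    libsizes = pd.Series(library_sizes, dtype=float).reindex(counts.sample_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"no length for features {missing[:5]}")
    if libsizes.isna().any():
        missing = libsizes.index[libsizes.isna()].tolist()
        raise ValueError(f"no library size for samples {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (libsizes <= 0).any():
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths.to_numpy() / 1e3, libsizes.to_numpy() / 1e6)
    rpkm = pd.DataFrame(
        counts.values / denom, index=counts.data.index, columns=counts.data.columns
    )
    return SignalMatrix(rpkm, units="RPKM")


def build_universe(
    enhancers: Sequence[GenomicInterval],
    rpkm: SignalMatrix,
    rpkm_threshold: float = 2.0,
    min_samples: int = 1,
    provenance: dict | None = None,
) -> EnhancerUniverse:
    """Keep enhancers expressed at >= ``rpkm_threshold`` RPKM (inclusive) in
    at least ``min_samples`` samples."""
    if rpkm_threshold <= 0:
        raise ValueError("rpkm_threshold must be strictly positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    ids = [e.id for e in enhancers]
    matrix = rpkm.subset_features(ids)
    passing = (matrix.values >= rpkm_threshold).sum(axis=1) >= min_samples
    kept = [e for e, ok in zip(enhancers, passing) if ok]
    if not kept:
        warnings.warn("no enhancer passes the RPKM threshold; empty universe")
    kept_ids = [e.id for e in kept]
    prov = dict(provenance or {})
    prov.update(
        {
            "rpkm_threshold": rpkm_threshold,
            "min_samples": min_samples,
            "n_samples": len(rpkm.sample_ids),
            "n_input_enhancers": len(ids),
            "n_retained_enhancers": len(kept),
        }
    )
    kept_rpkm = (
        matrix.subset_features(kept_ids)
        if kept_ids
        else SignalMatrix(matrix.data.iloc[:0], units=matrix.units)
    )
    return EnhancerUniverse(enhancers=kept, rpkm=kept_rpkm, provenance=prov)


def region_overlap_summary(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> dict:
    """Count set-A regions sharing >= 1 bp with any set-B region, and those unique to A."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in set_b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrs = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        ends = np.maximum.accumulate(np.array([e for _, e in spans]))
        arrs[chrom] = (starts, ends)
    n_overlap = 0
    for iv in set_a:
        se = arrs.get(iv.chrom)
        if se is None:
            continue
        starts, ends = se
        i = int(np.searchsorted(starts, iv.end))  # b spans starting before iv.end
        if i > 0 and ends[i - 1] > iv.start:
            n_overlap += 1
    return {
        "n_A": len(set_a),
        "n_A_overlapping_B": n_overlap,
        "n_A_unique": len(set_a) - n_overlap,
    }
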