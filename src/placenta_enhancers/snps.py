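"""GWAS SNP density in region sets versus the genome-wide background.

Density is SNPs per million base pairs: the count of catalog SNPs falling
inside a (pre-merged, non-overlapping) region set divided by the set's
total span in Mb.  The baseline divides the whole catalog by the total
genome size, and enrichment ratios are region density over baseline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

__all__ = ["annotate_snps_in_regions", "snp_density", "density_report"]


def _sorted_regions(regions: Sequence[GenomicInterval]):
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    arrs = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping regions {a.id} and {b.id}; merge regions first"
                )
        arrs[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            [iv.id for iv in ivs],
        )
    return arrs


def annotate_snps_in_regions(
    catalog: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Assign each SNP the id of its containing region, if any.

    A SNP at 0-based position p is contained in [start, end) iff
    start <= p < end (half-open: p == end is outside).
    """
    arrs = _sorted_regions(regions)
    assigned = []
    for chrom, pos in zip(catalog["chrom"], catalog["pos"]):
        entry = arrs.get(str(chrom))
        region_id = pd.NA
        if entry is not None:
            starts, ends, ids = entry
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                region_id = ids[i]
        assigned.append(region_id)
    out = catalog.copy()
    out["region_id"] = assigned
    out["in_region"] = out["region_id"].notna()
    return out


def snp_density(
    catalog: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    genome_size_bp: int,
) -> dict:
    """SNPs per Mb inside a region set, with genome-baseline enrichment ratio."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    annotated = annotate_snps_in_regions(catalog, regions)
    n_in = int(annotated["in_region"].sum())
    total_bp = int(sum(iv.length for iv in regions))
    density = n_in / (total_bp / 1e6) if total_bp else 0.0
    baseline = len(catalog) / (genome_size_bp / 1e6)
    return {
        "n_snps_overlapping": n_in,
        "total_bp": total_bp,
        "density_per_mb": density,
        "baseline_per_mb": baseline,
        "enrichment_ratio": density / baseline if baseline > 0 else np.nan,
    }


def density_report(
    catalog: pd.DataFrame,
    region_sets: dict[str, Sequence[GenomicInterval]],
    genome_size_bp: int,
) -> pd.DataFrame:
    """Density and enrichment for several named region sets (e.g. genes,
    enhancers) against the same catalog and genome baseline."""
    rows = []
    for name, regions in region_sets.items():
        d = snp_density(catalog, regions, genome_size_bp)
        d["region_set"] = name
        rows.append(d)
    cols = [
        "region_set",
        "n_snps_overlapping",
        "total_bp",
        "density_per_mb",
        "baseline_per_mb",
        "enrichment_ratio",
    ]
    return pd.DataFrame(rows)[cols]
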