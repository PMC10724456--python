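"""Enhancer-gene association and relationship statistics.

Nearest-gene assignment (enhancer interval to gene TSS by default),
enhancers-per-gene rank tables, hypergeometric gene-list overlap tests, and
enhancer-gene expression correlation across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, SignalMatrix

__all__ = [
    "nearest_gene",
    "enhancers_per_gene",
    "hypergeometric_overlap",
    "enhancer_gene_correlation",
]


def _gap_to_point(iv: GenomicInterval, pos: int) -> int:
    """Bases strictly between an interval and a 1-bp position (0 if inside)."""
    return max(0, iv.start - (pos + 1), pos - iv.end)


def _gap_to_span(iv: GenomicInterval, start: int, end: int) -> int:
    return max(0, iv.start - end, start - iv.end)


def nearest_gene(
    enhancers: list[GenomicInterval],
    genes: list[GeneModel],
    mode: str = "tss",
) -> pd.DataFrame:
    """Link each enhancer to its nearest gene on the same chromosome.

    ``mode='tss'`` minimizes the gap between the enhancer interval and the
    gene's TSS (regulatory targeting of promoters); ``mode='span'``
    minimizes the gap to the gene body.  Ties break to the lexicographically
    smallest gene_id.  Enhancers on chromosomes with no gene are unlinked
    (gene_id NA, flagged ``linked=False``).
    """
    if not genes:
        raise ValueError("gene set is empty")
    if mode not in ("tss", "span"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    rows = []
    for enh in enhancers:
        cands = by_chrom.get(enh.chrom, [])
        best = None
        for g in cands:
            if mode == "tss":
                gap = _gap_to_point(enh, g.tss)
            else:
                gap = _gap_to_span(enh, g.interval.start, g.interval.end)
            key = (gap, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g)
        if best is None:
            rows.append(
                {
                    "enhancer_id": enh.id,
                    "gene_id": pd.NA,
                    "distance_bp": pd.NA,
                    "linked": False,
                    "link_rule": "nearest_gene",
                }
            )
        else:
            (gap, _), g = best
            rows.append(
                {
                    "enhancer_id": enh.id,
                    "gene_id": g.gene_id,
                    "distance_bp": gap,
                    "linked": True,
                    "link_rule": "nearest_gene",
                }
            )
    return pd.DataFrame(rows)


def enhancers_per_gene(links: pd.DataFrame) -> pd.DataFrame:
    """Tally linked enhancers per gene, ranked descending (ties by gene_id)."""
    linked = links[links["linked"].astype(bool)] if len(links) else links
    if len(linked) == 0:
        return pd.DataFrame(columns=["gene_id", "n_enhancers", "rank"])
    counts = (
        linked.groupby("gene_id", sort=True)
        .size()
        .rename("n_enhancers")
        .reset_index()
    )
    counts = counts.sort_values(
        ["n_enhancers", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts


def hypergeometric_overlap(set_a, set_b, universe_size: int) -> dict:
    """Upper-tail hypergeometric test for the overlap of two gene lists.

    p = P(X >= k) for X ~ Hypergeometric(N=universe_size, K=|A|, n=|B|),
    i.e. the probability that two random lists of the same sizes drawn from
    the universe share at least the observed k members.  Enrichment only.
    """
    set_a, set_b = set(set_a), set(set_b)
    if universe_size < max(len(set_a), len(set_b)):
        raise ValueError("universe smaller than one of the sets")
    k = len(set_a & set_b)
    expected = len(set_a) * len(set_b) / universe_size if universe_size else 0.0
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_a), len(set_b)))
    return {
        "overlap": k,
        "size_a": len(set_a),
        "size_b": len(set_b),
        "universe_size": universe_size,
        "expected_overlap": expected,
        "p_value": min(1.0, p),
    }


def enhancer_gene_correlation(
    enhancer_rpkm: SignalMatrix,
    gene_expr: SignalMatrix,
    pairs: list[tuple[str, str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of enhancer transcription with gene expression.

    Computed over the shared samples for each (enhancer_id, gene_id) pair;
    ``pairs`` may be a link table (enhancer_id/gene_id columns) or explicit
    tuples.  Constant vectors give undefined r (flagged, r NaN).
    """
    if isinstance(pairs, pd.DataFrame):
        if "linked" in pairs.columns:
            pairs = pairs[pairs["linked"].astype(bool)]
        pair_list = list(zip(pairs["enhancer_id"], pairs["gene_id"]))
    else:
        pair_list = list(pairs)
    shared = [s for s in enhancer_rpkm.sample_ids if s in set(gene_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    e = enhancer_rpkm.data.loc[:, shared]
    g = gene_expr.data.loc[:, shared]
    rows = []
    for enh_id, gene_id in pair_list:
        x = e.loc[enh_id].to_numpy()
        y = g.loc[gene_id].to_numpy()
        if x.std() == 0 or y.std() == 0:
            rows.append(
                {
                    "enhancer_id": enh_id,
                    "gene_id": gene_id,
                    "pearson_r": np.nan,
                    "p_value": np.nan,
                    "defined": False,
                }
            )
            continue
        res = stats.pearsonr(x, y)
        rows.append(
            {
                "enhancer_id": enh_id,
                "gene_id": gene_id,
                "pearson_r": float(res.statistic),
                "p_value": float(res.pvalue),
                "defined": True,
            }
        )
    out = pd.DataFrame(
        rows, columns=["enhancer_id", "gene_id", "pearson_r", "p_value", "defined"]
    )
    out.attrs["n_samples"] = len(shared)
    return out
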