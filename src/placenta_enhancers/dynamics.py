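"""Gene-expression normalization and gestational dynamics.

Covers median-of-ratios size factors, Pearson correlation of expression with
gestational age (with Bonferroni classification into increasing/decreasing
genes), Benjamini-Hochberg adjustment, pairwise trimester differential
tests, z-score epoch trends, trophoblast cell-type signature scores, and the
delta-delta-Ct qPCR fold-change utility.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SampleRecord, SignalMatrix

__all__ = [
    "bonferroni_cutoff",
    "size_factors",
    "normalize_by_size_factors",
    "correlate_with_age",
    "bh_adjust",
    "pairwise_differential",
    "epoch_trends",
    "signature_score",
    "fold_change_ddct",
]


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / m over m tested associations."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def size_factors(counts: SignalMatrix) -> pd.Series:
    """Median-of-ratios library scale factors (Anders & Huber).

    s_j = median over features i with all-positive counts of
    counts(i, j) / geometric_mean_v counts(i, v).  Note the estimator is
    invariant to a common rescaling of all libraries; only relative library
    depth is identified.
    """
    values = counts.values
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with nonzero counts in every sample; size factors "
            "are undefined"
        )
    v = values[positive]
    log_geomean = np.mean(np.log(v), axis=1, keepdims=True)
    ratios = v / np.exp(log_geomean)
    return pd.Series(
        np.median(ratios, axis=0), index=counts.sample_ids, name="size_factor"
    )


def normalize_by_size_factors(counts: SignalMatrix) -> SignalMatrix:
    s = size_factors(counts)
    return SignalMatrix(counts.data.div(s, axis=1), units="normalized")


def _ages(samples: Sequence[SampleRecord], sample_ids: Sequence[str]) -> np.ndarray:
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in sample_ids if sid not in by_id]
    if missing:
        raise KeyError(f"samples absent from sample sheet: {missing}")
    return np.array([by_id[sid].gestational_age_weeks for sid in sample_ids])


def correlate_with_age(
    expr: SignalMatrix,
    samples: Sequence[SampleRecord],
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify genes as increasing/decreasing with gestational age.

    Per gene: Pearson r of expression versus gestational age in weeks, a
    two-sided p-value from the t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom, and the least-squares slope/intercept.  A gene
    is classified increasing when r > r_threshold and p < alpha / m
    (Bonferroni over the m testable genes), decreasing symmetrically, and
    unclassified otherwise.  Constant-expression genes have undefined r:
    they are flagged ``testable=False`` and excluded from m.
    """
    ages = _ages(samples, expr.sample_ids)
    if len(np.unique(ages)) < 3:
        raise ValueError("need >= 3 samples with distinct gestational ages")
    x = ages - ages.mean()
    sxx = float(x @ x)
    y = expr.values
    yc = y - y.mean(axis=1, keepdims=True)
    syy = (yc**2).sum(axis=1)
    sxy = yc @ x
    testable = syy > 0
    n = len(ages)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(testable, sxy / np.sqrt(sxx * syy), np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        slope = np.where(testable, sxy / sxx, 0.0)
    intercept = y.mean(axis=1) - slope * ages.mean()
    m = int(testable.sum())
    if m == 0:
        raise ValueError("no testable (non-constant) gene")
    cutoff = bonferroni_cutoff(alpha, m)
    cls = np.full(len(r), "unclassified", dtype=object)
    sig = testable & (p < cutoff)
    cls[sig & (r > r_threshold)] = "increasing"
    cls[sig & (r < -r_threshold)] = "decreasing"
    out = pd.DataFrame(
        {
            "gene_id": expr.feature_ids,
            "pearson_r": r,
            "p_value": p,
            "slope": slope,
            "intercept": intercept,
            "testable": testable,
            "class": cls,
        }
    )
    out.attrs["n_tested"] = m
    out.attrs["bonferroni_cutoff"] = cutoff
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_differential(
    expr: SignalMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.1,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group differential table over features (genes or enhancers).

    log2FC = log2((mean_B + eps) / (mean_A + eps)) with pseudocount eps;
    a two-sided two-sample t test per feature (Student pooled-variance by
    default, Welch optionally); Benjamini-Hochberg q-values.  A feature is
    flagged significant when |log2FC| >= log2(fc_threshold) and q < alpha.
    """
    set_a, set_b = set(group_a), set(group_b)
    overlap = set_a & set_b
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = expr.data.loc[:, list(group_a)].to_numpy()
    b = expr.data.loc[:, list(group_b)].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    # constant identical groups yield nan; no evidence of difference
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    q = bh_adjust(p)
    significant = (np.abs(log2fc) >= np.log2(fc_threshold)) & (q < alpha)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": log2fc,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "significant": significant,
        }
    )


def assign_epoch_bins(
    samples: Sequence[SampleRecord], n_bins: int = 5
) -> pd.Series:
    """Partition samples into age-ordered bins of near-equal size.

    Earlier bins absorb the remainder (36 samples, 5 bins -> 8,7,7,7,7).
    Age ties break by sample_id lexicographic order.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ordered = sorted(samples, key=lambda s: (s.gestational_age_weeks, s.sample_id))
    n = len(ordered)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    bins = {}
    idx = 0
    for b, size in enumerate(sizes, start=1):
        for s in ordered[idx : idx + size]:
            bins[s.sample_id] = b
        idx += size
    return pd.Series(bins, name="epoch_bin")


def epoch_trends(
    expr: SignalMatrix,
    samples: Sequence[SampleRecord],
    n_bins: int = 5,
) -> dict:
    """Per-gene z-scores summarized over gestational-age bins.

    Each gene's expression is z-score normalized across samples (mean 0,
    sd 1); samples are partitioned into ``n_bins`` age-ordered near-equal
    groups; the pooled z distribution per bin is summarized (n, mean,
    median, quartiles).  Constant genes are excluded with a warning.
    """
    bins = assign_epoch_bins(
        [s for s in samples if s.sample_id in set(expr.sample_ids)], n_bins
    )
    values = expr.values
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant gene(s) from z-score trends"
        )
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]
    zdf = pd.DataFrame(
        z, index=np.array(expr.feature_ids)[keep], columns=expr.sample_ids
    )
    rows = []
    for b in range(1, n_bins + 1):
        cols = bins.index[bins == b]
        pooled = zdf.loc[:, cols].to_numpy().ravel()
        rows.append(
            {
                "bin": b,
                "n_samples": len(cols),
                "n_values": pooled.size,
                "mean_z": pooled.mean(),
                "median_z": np.median(pooled),
                "q1_z": np.percentile(pooled, 25),
                "q3_z": np.percentile(pooled, 75),
            }
        )
    return {
        "zscores": zdf,
        "bin_of_sample": bins,
        "bin_summary": pd.DataFrame(rows),
    }


def signature_score(
    expr: SignalMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    samples: Sequence[SampleRecord],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Cell-type signature scores and pairwise trimester comparisons.

    The score of a sample for a gene set is the mean expression of the
    set's genes present in the matrix (a set with zero matched genes is an
    error).  Scores are compared between trimesters with the same
    fold-change + t-test machinery used for single features.
    """
    index = pd.Index(expr.feature_ids)
    rows = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in index]
        if not present:
            raise ValueError(f"gene set {name!r} has no gene present in the matrix")
        rows[name] = expr.data.loc[present].mean(axis=0)
    scores = SignalMatrix(pd.DataFrame(rows).T, units="normalized")
    groups: dict[str, list[str]] = {"I": [], "II": [], "III": []}
    for s in samples:
        if s.sample_id in set(expr.sample_ids):
            groups[s.trimester].append(s.sample_id)
    comparisons = {}
    pairs = [("I", "II"), ("I", "III"), ("II", "III")]
    for a, b in pairs:
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            comparisons[f"{a}_vs_{b}"] = pairwise_differential(
                scores, groups[a], groups[b], fc_threshold=fc_threshold, alpha=alpha
            )
    return {"scores": scores.data, "comparisons": comparisons}


def fold_change_ddct(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Comparative qPCR fold change of condition B over A by 2^-ddCt.

    ddCt = (Ct_target_B - Ct_ref_B) - (Ct_target_A - Ct_ref_A).
    """
    for v in (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return float(2.0 ** (-ddct))
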