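"""Total Functional Score of Enhancer Elements (TFSEE).

TFSEE integrates four measurements over an enhancer universe to score, per
sample, how active each transcription factor (TF) is at enhancers:

1. enhancer transcription (eRNA, from nascent-transcription data),
2. histone-mark enrichment at enhancers (H3K27ac and H3K4me1 ChIP),
3. motif predictions linking enhancers to TFs with a match p-value,
4. TF expression.

Pipeline:  per-enhancer min-max normalization N() makes signals comparable
across samples; enhancer activity A(s, e) = N(eRNA) * (N(K27ac) +
N(K4me1)) / 2 (eRNA is the defining signal — zero eRNA means zero
activity); a motif matrix M(e, t) holds per-TF motif strength (top-k hits
per enhancer, -log10 p, min-max scaled per TF); the score is
S_raw = (A @ M) * N_TF(expression), min-max scaled per TF to give S(s, t)
in [0, 1].  Samples are clustered hierarchically on 1 - Pearson distance
with average linkage, and TFs are ranked by the differential score
mean(S, late) - mean(S, early).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import SignalMatrix

__all__ = [
    "minmax_normalize",
    "enhancer_activity",
    "build_motif_matrix",
    "tfsee_scores",
    "cluster_samples",
    "differential_tfsee",
    "TFSEEResult",
]


def minmax_normalize(matrix: pd.DataFrame, axis: str = "per-feature") -> pd.DataFrame:
    """(x - min) / (max - min) along rows, columns, or globally.

    ``axis='per-feature'`` scales each row over its columns,
    ``'per-sample'`` each column, ``'global'`` the whole matrix.
    Zero-range slices map to all-zeros.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    if axis == "per-feature":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
    elif axis == "per-sample":
        lo = values.min(axis=0, keepdims=True)
        hi = values.max(axis=0, keepdims=True)
    elif axis == "global":
        lo = values.min()
        hi = values.max()
    else:
        raise ValueError(f"unknown axis {axis!r}")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def enhancer_activity(
    erna: SignalMatrix,
    k27ac: SignalMatrix,
    k4me1: SignalMatrix,
    combine: str = "mean_marks",
) -> pd.DataFrame:
    """Per-sample enhancer activity in [0, 1] (samples x enhancers).

    A = N(eRNA) * (N(K27ac) + N(K4me1)) / 2 with N the per-enhancer
    min-max across samples; ``combine='product'`` uses the full three-way
    product N(eRNA) * N(K27ac) * N(K4me1) instead.  Zero normalized eRNA
    forces zero activity under both rules.
    """
    if combine not in ("mean_marks", "product"):
        raise ValueError(f"unknown combine rule {combine!r}")
    for name, m in (("k27ac", k27ac), ("k4me1", k4me1)):
        if m.feature_ids != erna.feature_ids or m.sample_ids != erna.sample_ids:
            raise ValueError(f"{name} matrix indices differ from eRNA matrix")
    n_erna = minmax_normalize(erna.data, "per-feature")
    n_k27 = minmax_normalize(k27ac.data, "per-feature")
    n_k4 = minmax_normalize(k4me1.data, "per-feature")
    if combine == "mean_marks":
        act = n_erna * (n_k27 + n_k4) / 2.0
    else:
        act = n_erna * n_k27 * n_k4
    return act.T  # samples x enhancers


def build_motif_matrix(
    hits: pd.DataFrame,
    tf_ids: Sequence[str],
    top_k: int = 20,
    enhancer_ids: Sequence[str] | None = None,
    reduce: str = "max",
) -> pd.DataFrame:
    """Enhancer x TF motif-strength matrix in [0, 1].

    ``hits`` needs columns enhancer_id, tf_id and either ``match_p`` or
    ``match_strength`` (= -log10 match p).  Per enhancer only the ``top_k``
    strongest hits are kept (ties by tf_id then motif_id); strengths for
    the same (enhancer, TF) reduce by ``max`` (strongest site represents
    the TF; ``'sum'`` optional), then each TF column is min-max scaled
    across enhancers.  Absent pairs are 0.
    """
    if reduce not in ("max", "sum"):
        raise ValueError(f"unknown reduce rule {reduce!r}")
    tf_ids = list(tf_ids)
    unknown = set(hits["tf_id"]) - set(tf_ids)
    if unknown:
        raise ValueError(f"unknown tf_id in hit table: {sorted(unknown)[:5]}")
    hits = hits.copy()
    if "match_strength" not in hits.columns:
        if "match_p" not in hits.columns:
            raise ValueError("hit table needs match_strength or match_p")
        hits["match_strength"] = -np.log10(hits["match_p"].astype(float))
    if (hits["match_strength"] <= 0).any():
        raise ValueError("match strengths must be > 0 (match p < 1)")
    if "motif_id" not in hits.columns:
        hits["motif_id"] = ""
    hits = hits.sort_values(
        ["enhancer_id", "match_strength", "tf_id", "motif_id"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    kept = hits.groupby("enhancer_id", sort=False).head(top_k)
    agg = kept.groupby(["enhancer_id", "tf_id"])["match_strength"]
    reduced = (agg.max() if reduce == "max" else agg.sum()).reset_index()
    if enhancer_ids is None:
        enhancer_ids = sorted(reduced["enhancer_id"].unique())
    m = (
        reduced.pivot(index="enhancer_id", columns="tf_id", values="match_strength")
        .reindex(index=list(enhancer_ids), columns=tf_ids)
        .fillna(0.0)
    )
    return minmax_normalize(m.T, "per-feature").T  # per-TF scaling across enhancers


@dataclass
class TFSEEResult:
    """TFSEE score matrix with sample clustering and TF ranking."""

    scores: pd.DataFrame  # samples x TFs, per-TF min-max scaled to [0, 1]
    linkage: np.ndarray | None = None
    leaf_order: list[str] | None = None
    clades: dict | None = None
    differential: pd.DataFrame | None = None


def tfsee_scores(
    activity: pd.DataFrame,
    motif_matrix: pd.DataFrame,
    tf_expression: SignalMatrix,
) -> TFSEEResult:
    """Combine activity, motifs, and TF expression into per-sample TF scores.

    I = A @ M (samples x TFs); S_raw = I * N_TF(expression) with N_TF the
    per-TF min-max of expression across samples; S = per-TF min-max of
    S_raw.  The TF-expression matrix is TFs x samples (SignalMatrix
    orientation) and is transposed internally.
    """
    if list(activity.columns) != list(motif_matrix.index):
        raise ValueError("activity enhancers do not match motif-matrix enhancers")
    expr = tf_expression.data.T  # samples x TFs
    if list(expr.columns) != list(motif_matrix.columns):
        raise ValueError("TF expression ids do not match motif-matrix TFs")
    if list(expr.index) != list(activity.index):
        raise ValueError("TF expression samples do not match activity samples")
    intermediate = activity.to_numpy() @ motif_matrix.to_numpy()
    n_expr = minmax_normalize(expr.T, "per-feature").T  # per-TF across samples
    s_raw = pd.DataFrame(
        intermediate * n_expr.to_numpy(),
        index=activity.index,
        columns=motif_matrix.columns,
    )
    s = minmax_normalize(s_raw.T, "per-feature").T
    return TFSEEResult(scores=s)


def cluster_samples(scores: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering of samples on 1 - Pearson r.

    Returns the linkage matrix, dendrogram leaf order, and the 2-clade
    partition obtained by cutting at the root.  A sample whose score vector
    is constant has no defined correlation and is an error.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to cluster")
    values = scores.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(scores.index[sd == 0])
        raise ValueError(f"constant score vector for sample(s) {bad}")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(z)
    flat = hierarchy.fcluster(z, t=2, criterion="maxclust")
    clades = {
        int(c): [scores.index[i] for i in range(len(flat)) if flat[i] == c]
        for c in np.unique(flat)
    }
    return {
        "linkage": z,
        "leaf_order": [scores.index[i] for i in leaves],
        "clades": clades,
    }


def differential_tfsee(
    scores: pd.DataFrame,
    early_samples: Sequence[str],
    late_samples: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank TFs by differential score mean(late) - mean(early).

    Per TF: delta = mean over late samples minus mean over early samples of
    the scaled score, a two-sided pooled-variance t test, and a
    significance flag at p < alpha.  Output is ranked ascending by delta:
    most early-active TFs first, most late-active last (ties by tf_id).
    """
    early, late = list(early_samples), list(late_samples)
    overlap = set(early) & set(late)
    if overlap:
        raise ValueError(f"early/late groups overlap: {sorted(overlap)}")
    if len(early) < 2 or len(late) < 2:
        raise ValueError("each group needs >= 2 samples")
    e = scores.loc[early].to_numpy()
    l = scores.loc[late].to_numpy()
    delta = l.mean(axis=0) - e.mean(axis=0)
    t, p = stats.ttest_ind(l, e, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    out = pd.DataFrame(
        {
            "tf_id": scores.columns,
            "delta_tfsee": delta,
            "t_statistic": t,
            "p_value": p,
            "significant": p < alpha,
        }
    )
    out = out.sort_values(
        ["delta_tfsee", "tf_id"], ascending=[True, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def run_tfsee(
    erna: SignalMatrix,
    k27ac: SignalMatrix,
    k4me1: SignalMatrix,
    hits: pd.DataFrame,
    tf_expression: SignalMatrix,
    early_samples: Sequence[str],
    late_samples: Sequence[str],
    top_k: int = 20,
    alpha: float = 0.05,
    combine: str = "mean_marks",
) -> TFSEEResult:
    """End-to-end TFSEE: activity, motif matrix, scores, clustering, ranking."""
    activity = enhancer_activity(erna, k27ac, k4me1, combine=combine)
    motif_m = build_motif_matrix(
        hits,
        tf_ids=tf_expression.feature_ids,
        top_k=top_k,
        enhancer_ids=erna.feature_ids,
    )
    result = tfsee_scores(activity, motif_m, tf_expression)
    clustering = cluster_samples(result.scores)
    result.linkage = clustering["linkage"]
    result.leaf_order = clustering["leaf_order"]
    result.clades = clustering["clades"]
    result.differential = differential_tfsee(
        result.scores, early_samples, late_samples, alpha=alpha
    )
    return result
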