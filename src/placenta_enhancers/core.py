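"""Core genomic data model.

All coordinates are 0-based, half-open (BED convention) everywhere inside the
package; 1-based inputs (GTF, GWAS-catalog positions) are converted at the
parser boundary in :mod:`placenta_enhancers.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SampleRecord",
    "SignalMatrix",
    "AnalysisConfig",
    "interval_gap",
    "trimester_of_age",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome.

    The unit of enhancers, transcribed regulatory elements (TREs), gene
    spans, and SNP positions (length-1 intervals).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.id:
            object.__setattr__(
                self, "id", f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_id(self, new_id: str) -> "GenomicInterval":
        return replace(self, id=new_id)


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Base pairs strictly between the nearest edges of two intervals.

    0 for overlapping or bookended intervals; ``None`` for different
    chromosomes (no finite gap).
    """
    if a.chrom != b.chrom:
        return None
    return max(0, b.start - a.end, a.start - b.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene span plus its transcription start site.

    The TSS is the 5' end of the span: ``start`` on the + strand,
    ``end - 1`` on the - strand.
    """

    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.interval.id!r} has no strand; gene models "
                "require '+' or '-'"
            )

    @property
    def gene_id(self) -> str:
        return self.interval.id

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


TRIMESTER_NAMES = ("I", "II", "III")


def trimester_of_age(gestational_age_weeks: float) -> str:
    """Clinical trimester for a gestational age in weeks (I <14, II 14-27, III >=28)."""
    if gestational_age_weeks < 14:
        return "I"
    if gestational_age_weeks < 28:
        return "II"
    return "III"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    gestational_age_weeks: float
    trimester: str
    sex: str = "unknown"
    assays: tuple[str, ...] = ("rnaseq", "proseq", "k27ac", "k4me1")

    def __post_init__(self):
        if self.gestational_age_weeks <= 0:
            raise ValueError("gestational age must be positive")
        if self.trimester not in TRIMESTER_NAMES:
            raise ValueError(f"unknown trimester {self.trimester!r}")
        expected = trimester_of_age(self.gestational_age_weeks)
        if self.trimester != expected:
            raise ValueError(
                f"sample {self.sample_id}: trimester {self.trimester} "
                f"inconsistent with age {self.gestational_age_weeks} wk "
                f"(expected {expected})"
            )
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")
        known = {"rnaseq", "proseq", "k27ac", "k4me1"}
        bad = set(self.assays) - known
        if bad:
            raise ValueError(f"unknown assays {sorted(bad)}")


class SignalMatrix:
    """A features x samples matrix of nonnegative signal values.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds feature ids (enhancers, genes, TFs) and whose columns hold sample
    ids.  Missing values and negative entries are rejected: the pipeline has
    no missing-data rule, so adapters must impute upstream.
    """

    VALID_UNITS = ("counts", "RPKM", "normalized")

    def __init__(self, data: pd.DataFrame, units: str = "counts"):
        if units not in self.VALID_UNITS:
            raise ValueError(f"units must be one of {self.VALID_UNITS}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at feature {data.index[i]!r}, "
                f"sample {data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at feature "
                f"{data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self.data = data.astype(float)
        self.units = units

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def reindex_samples(self, sample_ids: Sequence[str]) -> "SignalMatrix":
        """Reorder columns to the sample sheet's order; absent samples error.

        The sample sheet is the sample-ordering authority for all matrices.
        """
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return SignalMatrix(self.data.loc[:, list(sample_ids)], self.units)

    def subset_features(self, feature_ids: Sequence[str]) -> "SignalMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        return SignalMatrix(self.data.loc[list(feature_ids)], self.units)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignalMatrix)
            and self.units == other.units
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:
        n, m = self.shape
        return f"SignalMatrix({n} features x {m} samples, units={self.units})"


@dataclass
class AnalysisConfig:
    """Tunable analysis thresholds with the study's published defaults.

    distal_min_gap_bp
        minimum base-pair gap between an enhancer and the nearest gene span
        for the enhancer to count as distal (strictly greater-than test).
    rpkm_threshold / min_samples
        an enhancer enters the expressed universe if its transcription is
        >= rpkm_threshold RPKM in at least min_samples samples.
    pearson_r_threshold / alpha
        gestational-age correlation classification cutoffs (Bonferroni
        applied to alpha over the number of testable genes).
    fold_change_threshold
        minimum fold difference for trimester differential calls.
    tfsee_top_k_motifs
        motif hits retained per enhancer when building the motif matrix.
    n_epoch_bins
        number of gestational-age bins for z-score trend summaries.
    """

    distal_min_gap_bp: int = 5000
    rpkm_threshold: float = 2.0
    min_samples: int = 1
    pearson_r_threshold: float = 0.7
    alpha: float = 0.05
    fold_change_threshold: float = 2.0
    tfsee_top_k_motifs: int = 20
    n_epoch_bins: int = 5
    pseudocount: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in (
            "distal_min_gap_bp",
            "rpkm_threshold",
            "min_samples",
            "pearson_r_threshold",
            "alpha",
            "fold_change_threshold",
            "tfsee_top_k_motifs",
            "n_epoch_bins",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def check_shared_chromosomes(
    set_a: Iterable[GenomicInterval],
    set_b: Iterable[GenomicInterval],
    label_a: str = "first",
    label_b: str = "second",
) -> None:
    """Warn when two interval sets share no chromosome names.

    Chromosome names are compared by exact string match; a disjoint
    namespace usually means mixed naming dialects ("chr1" vs "1").
    """
    chroms_a = {iv.chrom for iv in set_a}
    chroms_b = {iv.chrom for iv in set_b}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        warnings.warn(
            f"{label_a} and {label_b} interval sets share no chromosome "
            "names; check naming dialects",
            stacklevel=2,
        )
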