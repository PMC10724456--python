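"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED6 intervals, minimal GTF gene annotation, TSV signal
matrices (header row = sample ids, first column = feature ids), sample-sheet
TSV, GWAS-catalog-style SNP TSV, and TSV/JSON result files.

Writers are deterministic: fixed column order, fixed row order, floats
rendered with 6 significant digits, so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, SampleRecord, SignalMatrix

FLOAT_FORMAT = "%.6g"

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_gene_annotation",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_snp_catalog",
    "write_snp_catalog",
    "write_table",
    "write_json",
    "file_sha256",
]


class ParseError(ValueError):
    """A malformed record in an input file, with file and line context."""


def _parse_error(path, lineno, msg) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; ids from column 4 when present.

    Coordinates are taken verbatim as 0-based half-open.  Missing names are
    synthesized as ``chrom:start-end``.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise _parse_error(
                    path, lineno, f"non-integer coordinates {fields[1:3]}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, id=name)
                )
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n"
            )


_GTF_GENE_ID = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_gene_annotation(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6 or minimal GTF.

    GTF records are 1-based inclusive and are converted to 0-based half-open
    here; a gene's span is the union (envelope) of all its feature lines.
    ``fmt`` is inferred from the file extension when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if fmt == "bed":
        return _genes_from_bed(path)
    if fmt == "gtf":
        return _genes_from_gtf(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _genes_from_bed(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: dict[str, GenomicInterval] = {}
    for iv in read_intervals(path):
        if iv.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {iv.id!r} missing strand")
        if iv.id in seen:
            if seen[iv.id] != iv:
                raise ParseError(
                    f"{path}: duplicate gene id {iv.id!r} with conflicting "
                    "coordinates"
                )
            continue
        seen[iv.id] = iv
        genes.append(GeneModel(iv))
    return genes


def _genes_from_gtf(path: Path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise _parse_error(path, lineno, "fewer than 9 GTF columns")
            chrom, start1, end1, strand, attrs = (
                fields[0],
                fields[3],
                fields[4],
                fields[6],
                fields[8],
            )
            if strand not in ("+", "-"):
                raise _parse_error(path, lineno, "missing strand")
            m = _GTF_GENE_ID.search(attrs)
            if not m:
                raise _parse_error(path, lineno, "no gene_id attribute")
            gene_id = m.group(1)
            try:
                start = int(start1) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            if not 0 <= start < end:
                raise _parse_error(path, lineno, f"invalid span {start1}-{end1}")
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
                order.append(gene_id)
            else:
                if rec["chrom"] != chrom or rec["strand"] != strand:
                    raise _parse_error(
                        path,
                        lineno,
                        f"gene {gene_id!r} spans conflicting chrom/strand",
                    )
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
    return [
        GeneModel(
            GenomicInterval(
                spans[g]["chrom"],
                spans[g]["start"],
                spans[g]["end"],
                strand=spans[g]["strand"],
                id=g,
            )
        )
        for g in order
    ]


def read_matrix(path: str | Path, units: str = "counts") -> SignalMatrix:
    """Read a features x samples TSV matrix.

    Non-numeric or negative cells, missing values, and duplicated ids are
    all rejected (with coordinates where possible).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: non-numeric or missing cell {df.iat[r, c]!r} at "
            f"feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        return SignalMatrix(numeric, units=units)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    matrix.data.to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature_id"
    )


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "gestational_age_weeks",
    "trimester",
    "sex",
    "assays",
]


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicated sample ids {dups}")
    records = []
    for _, row in df.iterrows():
        assays = tuple(a for a in str(row["assays"]).split(",") if a)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                gestational_age_weeks=float(row["gestational_age_weeks"]),
                trimester=row["trimester"],
                sex=row["sex"],
                assays=assays,
            )
        )
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "gestational_age_weeks": [s.gestational_age_weeks for s in samples],
            "trimester": [s.trimester for s in samples],
            "sex": [s.sex for s in samples],
            "assays": [",".join(s.assays) for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


SNP_COLUMNS = ["snp_id", "chrom", "pos_1based", "trait"]


def read_snp_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style SNP table.

    Input positions follow the public catalog's 1-based convention and are
    converted to an internal 0-based ``pos`` column here.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "trait": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: SNP catalog missing columns {missing}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ParseError(f"{path}: duplicated snp ids {dups[:5]}")
    pos = df["pos_1based"].astype(int) - 1
    if (pos < 0).any():
        raise ParseError(f"{path}: 1-based position < 1")
    out = df[["snp_id", "chrom", "trait"]].copy()
    out["pos"] = pos
    return out[["snp_id", "chrom", "pos", "trait"]]


def write_snp_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write the internal 0-based catalog back to the 1-based TSV format."""
    out = pd.DataFrame(
        {
            "snp_id": catalog["snp_id"],
            "chrom": catalog["chrom"],
            "pos_1based": catalog["pos"].astype(int) + 1,
            "trait": catalog["trait"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV result writer (6 significant digits)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
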