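"""Readers and writers for the tabular and genomic-interval formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention).  The TSS of a
``+`` strand gene is its ``start``; for a ``-`` strand gene it is ``end - 1``.
Tables are tab-separated UTF-8 with ``#`` comment lines allowed.  Every writer
round-trips through its reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SampleSheet",
    "CountMatrix",
    "FeatureAnnotation",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_bed",
    "write_bed",
    "read_methylation",
    "write_methylation",
    "read_bedgraph",
    "write_bedgraph",
    "write_json_summary",
]

_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its accepted grammar."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample", "group", "genotype", "stage", "cross", "sex"]


@dataclass
class SampleSheet:
    """Study metadata: one row per sequenced embryo.

    ``stage`` is the somite count at dissection; ``cross`` records the
    direction of the reciprocal cross; ``sex`` is recorded but carries no
    modelled effect.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.data["sample"].duplicated().any():
            dups = self.data.loc[self.data["sample"].duplicated(), "sample"].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        self.data = self.data.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()

    @property
    def groups(self) -> pd.Series:
        """Series mapping sample id -> group label, in sheet order."""
        return self.data.set_index("sample")["group"]

    def samples_of(self, group: str) -> list[str]:
        sel = self.data.loc[self.data["group"] == group, "sample"]
        return sel.tolist()


def read_sample_sheet(path) -> SampleSheet:
    df = _read_tsv(path)
    df["sample"] = df["sample"].astype(str)
    df["stage"] = df["stage"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix.

    ``kind`` distinguishes gene counts, repeat-locus counts and the
    maternal/paternal allele-resolved matrices.
    """

    data: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("count matrix contains non-integer cells")
            self.data = self.data.round().astype(np.int64)
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative values")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, features=None, samples=None) -> "CountMatrix":
        df = self.data
        if features is not None:
            df = df.loc[features]
        if samples is not None:
            df = df[list(samples)]
        return CountMatrix(df.copy(), kind=self.kind)


def read_counts(path, kind: str = "gene") -> CountMatrix:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a feature id column plus counts")
    feat_col = df.columns[0]
    df[feat_col] = df[feat_col].astype(str)
    df = df.set_index(feat_col)
    df.index.name = "feature"
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad = df.index[numeric.isna()][0]
            raise FormatError(f"{path}: non-numeric count for feature {bad!r} in {col}")
        if not np.allclose(numeric, np.round(numeric)):
            bad = df.index[~np.isclose(numeric, np.round(numeric))][0]
            raise FormatError(f"{path}: non-integer count for feature {bad!r} in {col}")
        df[col] = numeric.round().astype(np.int64)
    return CountMatrix(df, kind=kind)


def write_counts(counts: CountMatrix, path) -> None:
    out = counts.data.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genomic intervals (BED6 + optional subfamily/family columns)
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class FeatureAnnotation:
    """Genomic intervals with optional repeat lineage columns.

    Rows are sorted by (chrom, start).  For repeat annotations the extra
    ``subfamily`` and ``family`` columns carry the RepeatMasker lineage; gene
    annotations leave them empty.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in BED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df.loc[df["start"] >= df["end"]].iloc[0]
                raise FormatError(
                    f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            unknown = set(df["strand"]) - _STRANDS
            if unknown:
                raise FormatError(f"unknown strand symbol(s): {sorted(unknown)}")
        self.data = df.sort_values(["chrom", "start", "end", "name"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def names(self) -> pd.Series:
        return self.data["name"]

    def tss(self) -> pd.Series:
        """Transcription start positions keyed by feature name.

        ``start`` on the + strand, ``end - 1`` on the - strand; intervals on
        ``.`` use ``start``.
        """
        pos = np.where(self.data["strand"] == "-", self.data["end"] - 1, self.data["start"])
        return pd.Series(pos, index=self.data["name"].to_numpy(), name="tss")


def read_bed(path) -> FeatureAnnotation:
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED fields, got {len(parts)}")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
                "name": parts[3],
                "score": parts[4],
                "strand": parts[5],
            }
            if len(parts) >= 7:
                row["subfamily"] = parts[6]
            if len(parts) >= 8:
                row["family"] = parts[7]
            rows.append(row)
    columns = BED_COLUMNS + ["subfamily", "family"]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=columns).astype({"start": np.int64, "end": np.int64})
    for extra in ("subfamily", "family"):
        if extra not in df.columns:
            df[extra] = ""
    df = df.fillna({"subfamily": "", "family": ""})
    return FeatureAnnotation(df)


def write_bed(annotation: FeatureAnnotation, path) -> None:
    df = annotation.data
    with open(path, "wt", encoding="utf-8") as fh:
        for row in df.itertuples(index=False):
            fields = [
                row.chrom,
                str(row.start),
                str(row.end),
                row.name,
                str(row.score),
                row.strand,
            ]
            if getattr(row, "subfamily", "") or getattr(row, "family", ""):
                fields.append(getattr(row, "subfamily", ""))
                fields.append(getattr(row, "family", ""))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# CpG methylation tables
# ---------------------------------------------------------------------------


def read_methylation(path) -> pd.DataFrame:
    """Read a per-CpG beta-value table: chrom, pos, one beta column per sample.

    Beta values are methylation fractions in [0, 1]; missing calls are NA and
    are excluded per CpG downstream, never imputed.  Positions are sorted and
    must be unique within a chromosome.
    """
    df = _read_tsv(path)
    if df.empty and df.shape[1] == 0:
        return pd.DataFrame(columns=["chrom", "pos"])
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise FormatError(f"{path}: first two columns must be 'chrom' and 'pos'")
    df["pos"] = df["pos"].astype(np.int64)
    beta_cols = list(df.columns[2:])
    for col in beta_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ((vals < 0) | (vals > 1))
        if bad.any():
            raise FormatError(f"{path}: beta outside [0,1] in column {col}")
        df[col] = vals
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicate CpG positions")
    return df


def write_methylation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stranded coverage (bedGraph)
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track into a (chrom, start, end, value) frame."""
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            value = float(parts[3])
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage")
            rows.append((parts[0], start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64, "value": float})
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bedgraph(track: pd.DataFrame, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for row in track.itertuples(index=False):
            val = f"{row.value:g}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{val}\n")


def write_json_summary(summary: dict, path) -> None:
    """Write a run summary deterministically (sorted keys, no timestamps)."""
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
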