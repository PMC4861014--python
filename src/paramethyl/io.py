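"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions: cytosine reports are 1-based (Bismark cytosine /
CX report dialect); bins, BED intervals and gene annotations are 0-based
half-open.  Conversion happens only here and in :mod:`paramethyl.methylome`
at the parse/write boundary.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path, IO]

#: Columns of the cytosine-report dialect (Bismark CX style).
REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]

CONTEXTS = ("CG", "CHG", "CHH")


class CytosineReportError(ValueError):
    """Malformed cytosine report line, with its 1-based line number."""


def read_cytosine_report(source: PathLike) -> pd.DataFrame:
    """Read a Bismark-style cytosine report TSV into a DataFrame.

    Columns: chrom, pos (1-based), strand (+/-), meth, unmeth, context
    (CG/CHG/CHH), trinucleotide.  Malformed lines raise
    :class:`CytosineReportError` naming the offending line.
    """
    try:
        df = pd.read_csv(
            source,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=REPORT_COLUMNS).astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}
        )

    for col in ("pos", "meth", "unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != np.floor(coerced))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise CytosineReportError(
                f"line {line}: non-integer value in column '{col}'"
            )
        df[col] = coerced.astype(np.int64)

    if df.shape[1] != len(REPORT_COLUMNS):
        raise CytosineReportError(
            f"expected {len(REPORT_COLUMNS)} tab-separated columns, got {df.shape[1]}"
        )
    # pandas pads missing trailing fields with NaN; flag those rows too
    incomplete = df[REPORT_COLUMNS].isna().any(axis=1)
    if incomplete.any():
        line = int(np.flatnonzero(incomplete.to_numpy())[0]) + 1
        raise CytosineReportError(f"line {line}: wrong number of columns")

    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
        raise CytosineReportError(
            f"line {line}: unknown context {df['context'].iloc[line - 1]!r}"
        )
    bad_strand = ~df["strand"].isin(("+", "-"))
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise CytosineReportError(
            f"line {line}: strand must be '+' or '-', got {df['strand'].iloc[line - 1]!r}"
        )
    for col in ("meth", "unmeth"):
        neg = df[col] < 0
        if neg.any():
            line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise CytosineReportError(f"line {line}: negative count in column '{col}'")
    nonpos = df["pos"] < 1
    if nonpos.any():
        line = int(np.flatnonzero(nonpos.to_numpy())[0]) + 1
        raise CytosineReportError(f"line {line}: position must be >= 1")
    return df


def write_cytosine_report(records: pd.DataFrame, sink: PathLike) -> None:
    """Write records in the cytosine-report dialect (no header)."""
    out = records.copy()
    if "trinucleotide" not in out.columns:
        out["trinucleotide"] = "NNN"
    out[REPORT_COLUMNS].to_csv(sink, sep="\t", header=False, index=False)


def read_count_matrix(source: PathLike, id_column: str | None = None) -> pd.DataFrame:
    """Read a TSV count/expression matrix (first column = row id, header = samples)."""
    df = pd.read_csv(source, sep="\t")
    id_col = id_column or df.columns[0]
    return df.set_index(id_col)


def write_count_matrix(matrix: pd.DataFrame, sink: PathLike, id_name: str = "id") -> None:
    matrix.rename_axis(id_name).to_csv(sink, sep="\t")


def read_design(source: PathLike) -> pd.Series:
    """Read a two-column (library, genotype) design TSV into a Series."""
    df = pd.read_csv(source, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_de_table(source: PathLike) -> pd.DataFrame:
    """Differential-expression table: gene, log2fc (wt over sulf), padj."""
    df = pd.read_csv(source, sep="\t")
    df.columns = ["gene", "log2fc", "padj"] + list(df.columns[3:])
    return df


def read_annotation(source: PathLike) -> pd.DataFrame:
    """Gene annotation from BED (>=4 cols) or 4-column TSV.

    Returns columns gene, chrom, start, end (0-based half-open) and, when
    present, strand.
    """
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype={0: str})
    first = str(df.iloc[0, 0]).lower() if len(df) else ""
    if first in ("chrom", "gene", "chromosome"):  # header row present
        df = pd.read_csv(source, sep="\t", comment="#", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        cols = ["gene", "chrom", "start", "end"]
        return df[[c for c in cols + ["strand"] if c in df.columns]]
    if df.shape[1] >= 4:
        out = df.iloc[:, :4].copy()
        out.columns = ["chrom", "start", "end", "gene"]
        if df.shape[1] >= 6:
            out["strand"] = df.iloc[:, 5]
        return out[["gene", "chrom", "start", "end"] + (["strand"] if "strand" in out else [])]
    raise ValueError("annotation needs at least 4 columns (BED or gene/chrom/start/end)")


def read_qpcr_table(source: PathLike) -> pd.DataFrame:
    """qPCR Cq table: sample, target, replicate, cq; 'NA' means no amplification.

    No-amplification wells come back with Cq = +inf so downstream
    arithmetic (surviving fraction -> 0) needs no special casing.
    """
    df = pd.read_csv(
        source, sep="\t", dtype={"sample": str, "target": str}, na_values=["NA", "na"]
    )
    df.columns = [c.lower() for c in df.columns]
    df["cq"] = df["cq"].astype(float).fillna(math.inf)
    return df


def write_bed(intervals: pd.DataFrame, sink: PathLike) -> None:
    """Write a BED6 file (chrom, start, end, name, score, strand)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    intervals[cols].to_csv(sink, sep="\t", header=False, index=False)


def read_bed(source: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, sep="\t", header=None, dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df
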