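"""Readers and writers for the tabular formats used across the pipeline.

The central interchange format is the *cytosine report*: one row per
cytosine per strand with columns

    chrom  pos(1-based)  strand  count_methylated  count_unmethylated  context

which is also the column layout of a Bismark CX report (there
``count_methylated`` / ``count_unmethylated`` are the C and T read
counts and the trailing tri-nucleotide column is ignored).  Internally
positions are 0-based; conversion happens at the file boundary.
"""

from __future__ import annotations

import pandas as pd

REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
]


def read_cytosine_report(path, dialect: str = "native") -> pd.DataFrame:
    """Read a per-site cytosine count table.

    ``dialect="native"`` expects a header line with the columns above;
    ``dialect="cx"`` reads a headerless Bismark CX-style report
    (chrom, pos, strand, count_meth, count_unmeth, context, [tri-context]).
    Positions are converted to 0-based.
    """
    if dialect == "native":
        df = pd.read_csv(path, sep="\t")
        missing = set(REPORT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cytosine report missing columns: {sorted(missing)}")
        df = df[REPORT_COLUMNS].copy()
    elif dialect == "cx":
        df = pd.read_csv(path, sep="\t", header=None)
        df = df.iloc[:, :6]
        df.columns = REPORT_COLUMNS
    else:
        raise ValueError(f"unknown cytosine-report dialect: {dialect!r}")
    df["pos"] = df["pos"].astype(int) - 1
    df["count_methylated"] = df["count_methylated"].astype(int)
    df["count_unmethylated"] = df["count_unmethylated"].astype(int)
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    out = df[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> pd.DataFrame:
    """Read a per-gene count table: columns gene, count_ck, count_atr."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "count_ck", "count_atr"):
        if col not in df.columns:
            raise ValueError(f"expression table missing column {col!r}")
    return df


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open) with an optional name column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"locus_{i}" for i in range(len(df))]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write intervals as BED6: chrom start end name score strand."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", index=False, header=False, float_format="%.4g")
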