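"""Methylation of miRNA precursor loci.

miRNA genes can themselves be silenced or activated by DNA methylation
of the loci that generate them.  For each precursor interval the pooled
methylation level (all contexts together) is computed per condition,
expressed as ``log2(ML_treatment / ML_control)``, and screened with a
two-fold (|log2| >= 1) filter.

The package ships a small reference table
(``data/mirna_loci_ml.tsv``) of published per-locus methylation levels
at rice miRNA precursor loci under atrazine exposure versus control,
with the log2 ratio as originally published.  For a subset of rows the
published "log2" column is actually the raw ML ratio (e.g. 0.45 / 0.21
given as 2.14 instead of log2(2.14...) = 1.10); recomputation flags
those rows as inconsistent rather than silently correcting them.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def locus_methylation(calls: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Pooled methylation level per locus for one condition.

    Parameters
    ----------
    calls
        Per-site table with ``chrom, pos, count_methylated, total``.
    loci
        Intervals with ``chrom, start, end, name`` (0-based half-open).

    Returns
    -------
    One row per locus: ``name, chrom, start, end, count_methylated,
    total, n_sites, ml``.  Loci with zero covered cytosines get
    ``ml = NaN``.
    """
    by_chrom = {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        g = grp.sort_values("pos")
        pos = g["pos"].to_numpy()
        cmc = np.concatenate([[0], np.cumsum(g["count_methylated"].to_numpy())])
        ctot = np.concatenate([[0], np.cumsum(g["total"].to_numpy())])
        by_chrom[chrom] = (pos, cmc, ctot)
    rows = []
    for _, locus in loci.iterrows():
        chrom, s, e = locus["chrom"], int(locus["start"]), int(locus["end"])
        mc = tot = n = 0
        if chrom in by_chrom:
            pos, cmc, ctot = by_chrom[chrom]
            lo, hi = np.searchsorted(pos, s), np.searchsorted(pos, e)
            mc = int(cmc[hi] - cmc[lo])
            tot = int(ctot[hi] - ctot[lo])
            n = int(hi - lo)
        rows.append(
            {
                "name": locus["name"],
                "chrom": chrom,
                "start": s,
                "end": e,
                "count_methylated": mc,
                "total": tot,
                "n_sites": n,
                "ml": mc / tot if tot > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def log2_ml_ratio(ml_treatment: float, ml_control: float) -> float:
    """log2 of the treatment/control methylation-level ratio.

    NaN (with a debug log) when either level is zero or missing --
    ratios are undefined for uncovered or fully unmethylated loci.
    Full precision; round only at reporting.
    """
    if (
        ml_treatment is None
        or ml_control is None
        or not np.isfinite(ml_treatment)
        or not np.isfinite(ml_control)
        or ml_treatment <= 0
        or ml_control <= 0
    ):
        logger.debug("undefined ML ratio for (%s, %s)", ml_treatment, ml_control)
        return float("nan")
    return float(np.log2(ml_treatment / ml_control))


def compare_locus_methylation(
    ml_treatment: pd.DataFrame, ml_control: pd.DataFrame
) -> pd.DataFrame:
    """Join per-condition locus tables and compute log2 ratios.

    Loci with undefined ML in either condition are retained with NaN
    ratio (and are excluded by :func:`two_fold_filter`).
    """
    t = ml_treatment[["name", "ml"]].rename(columns={"ml": "ml_treatment"})
    c = ml_control[["name", "ml"]].rename(columns={"ml": "ml_control"})
    df = t.merge(c, on="name", how="outer")
    df["log2_ratio"] = [
        log2_ml_ratio(a, b) for a, b in zip(df["ml_treatment"], df["ml_control"])
    ]
    df["direction"] = np.where(df["log2_ratio"] > 0, "up", "down")
    df.loc[~np.isfinite(df["log2_ratio"]), "direction"] = "na"
    return df


def two_fold_filter(records: pd.DataFrame, min_abs_log2: float = 1.0) -> pd.DataFrame:
    """Keep loci whose |log2 ML ratio| meets the two-fold criterion."""
    keep = records["log2_ratio"].abs() >= min_abs_log2
    return records[keep & np.isfinite(records["log2_ratio"])].reset_index(drop=True)


def reported_mirna_loci() -> pd.DataFrame:
    """Published rice miRNA-locus methylation levels (treatment, control).

    Returns the packaged reference table with recomputed log2 ratios and
    a ``consistent`` flag: True when the printed log2 column agrees with
    ``round(log2(ml_treatment / ml_control), 2)`` to within 0.01.  The
    inconsistent rows (where the raw ratio was printed in place of its
    log2) are flagged, not corrected.
    """
    ref = importlib.resources.files("dmrkit") / "data" / "mirna_loci_ml.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["recomputed_log2"] = [
        log2_ml_ratio(a, b) for a, b in zip(df["ml_treatment"], df["ml_control"])
    ]
    df["consistent"] = (
        (df["recomputed_log2"].round(2) - df["reported_log2_ratio"]).abs() <= 0.01
    )
    return df
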