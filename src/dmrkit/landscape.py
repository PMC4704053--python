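"""Methylation landscape summaries.

All summaries pool read counts (ML = sum mC / sum(mC + non-mC)) rather
than averaging per-site levels: pooling matches the definition of the
methylation level and automatically downweights low-coverage sites.
Windows with no covered site of a context get ML = NaN for it.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from dmrkit.genome import CONTEXTS, GeneModel, REGIONS

logger = logging.getLogger(__name__)


def context_composition(calls: pd.DataFrame) -> pd.Series:
    """Fraction of methylated cytosines falling in each context.

    Computed over sites with ``is_methylated`` true; the fractions sum
    to 1 whenever any methylated site exists.  With no methylated site
    all fractions are NaN (warned).
    """
    mc = calls[calls["is_methylated"]]
    n = len(mc)
    if n == 0:
        warnings.warn("no methylated sites; context composition undefined")
        return pd.Series({c: np.nan for c in CONTEXTS})
    counts = mc["context"].value_counts()
    return pd.Series({c: counts.get(c, 0) / n for c in CONTEXTS})


def _pool_windows(df: pd.DataFrame, start_col: str) -> pd.DataFrame:
    pooled = df.groupby(["chrom", start_col, "context"], as_index=False).agg(
        count_methylated=("count_methylated", "sum"),
        total=("total", "sum"),
        n_sites=("pos", "size"),
    )
    pooled["ml"] = pooled["count_methylated"] / pooled["total"]
    return pooled


def sliding_window_levels(
    calls: pd.DataFrame,
    width: int = 200,
    step: int | None = None,
) -> pd.DataFrame:
    """Per-context pooled methylation level in windows tiling each chromosome.

    Windows start at 0, width, 2*width, ... (``step`` defaults to
    ``width``, i.e. non-overlapping; ``step < width`` gives overlapping
    sliding windows and a site then contributes to every window covering
    it).  Only windows containing at least one covered site of a context
    appear for that context.

    Returns columns ``chrom, start, end, context, count_methylated,
    total, n_sites, ml``.
    """
    if width < 1 or (step is not None and step < 1):
        raise ValueError("width and step must be >= 1")
    step = width if step is None else step
    # a site at pos lies in every window whose start is in (pos-width, pos]
    # and on the step grid; expand each site over those window starts
    df = calls
    first = ((df["pos"] - width) // step + 1).clip(lower=0)
    last = df["pos"] // step
    reps = (last - first + 1).to_numpy()
    expanded = df.loc[df.index.repeat(reps)].copy()
    offsets = (
        np.concatenate([np.arange(r) for r in reps]) if len(reps) else np.empty(0, int)
    )
    expanded["_wstart"] = (np.repeat(first.to_numpy(), reps) + offsets) * step
    pooled = _pool_windows(expanded, "_wstart").rename(columns={"_wstart": "start"})
    pooled["end"] = pooled["start"] + width
    cols = ["chrom", "start", "end", "context", "count_methylated", "total", "n_sites", "ml"]
    return pooled[cols].sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def chromosome_profile(
    calls: pd.DataFrame,
    bin_size: int = 10_000,
    smooth_bins: int = 5,
) -> pd.DataFrame:
    """Chromosome-scale binned per-context levels with moving-average smoothing.

    Pools counts in fixed ``bin_size`` bins (same rule as
    :func:`sliding_window_levels`) and adds a centred moving average of
    the binned ML over ``smooth_bins`` bins (``ml_smooth``; NaN bins are
    skipped by the average).  ``smooth_bins=0`` disables smoothing.
    """
    prof = sliding_window_levels(calls, width=bin_size, step=bin_size)
    if smooth_bins and smooth_bins > 1:
        pieces = []
        for (chrom, ctx), grp in prof.groupby(["chrom", "context"], sort=False):
            grp = grp.sort_values("start").copy()
            # reindex onto the full bin grid so the moving window is positional
            grid = np.arange(0, grp["start"].max() + bin_size, bin_size)
            ml = grp.set_index("start")["ml"].reindex(grid)
            grp["ml_smooth"] = (
                ml.rolling(smooth_bins, center=True, min_periods=1).mean().loc[grp["start"]].to_numpy()
            )
            pieces.append(grp)
        prof = pd.concat(pieces, ignore_index=True)
    else:
        prof["ml_smooth"] = prof["ml"]
    return prof.sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def feature_metaprofile(
    calls: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    n_bins: int = 20,
    regions: Sequence[str] = REGIONS,
    subfeatures: bool = False,
) -> pd.DataFrame:
    """Average methylation metaprofile across genes.

    Each gene region is rescaled to ``n_bins`` bins oriented 5'→3' on
    the gene's own strand; counts are pooled across genes per bin and
    context.  With ``subfeatures=True``, 5'UTR/CDS/intron/3'UTR
    intervals (where annotated) are profiled the same way.  Genes with
    empty regions are skipped.

    Returns columns ``region, bin, context, count_methylated, total,
    n_sites, ml``.
    """
    targets: list[tuple[str, GeneModel, tuple[int, int]]] = []
    for gm in gene_models:
        for region in regions:
            iv = gm.region(region)
            if iv[1] > iv[0]:
                targets.append((region, gm, iv))
        if subfeatures:
            for name, ivs in gm.subfeatures.items():
                for iv in ivs:
                    if iv[1] > iv[0]:
                        targets.append((name, gm, iv))

    # per-chromosome sorted site arrays for fast interval slicing
    by_chrom = {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        g = grp.sort_values("pos")
        by_chrom[chrom] = (
            g["pos"].to_numpy(),
            g["count_methylated"].to_numpy(),
            g["total"].to_numpy(),
            g["context"].to_numpy(),
        )

    rows = []
    for region, gm, (s, e) in targets:
        if gm.chrom not in by_chrom:
            continue
        pos, mc, tot, ctx = by_chrom[gm.chrom]
        lo, hi = np.searchsorted(pos, s), np.searchsorted(pos, e)
        if hi == lo:
            continue
        p = pos[lo:hi]
        rel = (p - s) / (e - s)
        if gm.strand == "-":
            rel = 1 - rel - 1e-12  # orient 5'→3' on the gene strand
        b = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        rows.append(
            pd.DataFrame(
                {
                    "region": region,
                    "bin": b,
                    "context": ctx[lo:hi],
                    "count_methylated": mc[lo:hi],
                    "total": tot[lo:hi],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["region", "bin", "context", "count_methylated", "total", "n_sites", "ml"]
        )
    df = pd.concat(rows, ignore_index=True)
    pooled = df.groupby(["region", "bin", "context"], as_index=False).agg(
        count_methylated=("count_methylated", "sum"),
        total=("total", "sum"),
        n_sites=("total", "size"),
    )
    pooled["ml"] = pooled["count_methylated"] / pooled["total"]
    return pooled.sort_values(["region", "bin", "context"]).reset_index(drop=True)
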