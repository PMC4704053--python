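"""Differential methylation between two conditions.

For every gene region (upstream / genebody / downstream) and sequence
context, reads supporting methylation are pooled, normalised as RKTM
(reads per kilobase of feature per million methylation-informative
reads), and compared between treatment and control with a two-sided
Fisher's exact test on the pooled (methylated, unmethylated) counts.
A feature is differentially methylated when its Benjamini-Hochberg FDR
is below 0.05 *and* the RKTM ratio between conditions exceeds 2 (in
either direction); the hyper/hypo direction comes from the methylation
levels.  The same test applied to fixed windows, followed by merging of
adjacent significant windows of equal context and direction, yields
differentially methylated regions (DMRs).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dmrkit.calling import benjamini_hochberg
from dmrkit.genome import CONTEXTS, GeneModel, REGIONS

logger = logging.getLogger(__name__)

#: pseudocount added to RKTM numerators only when one side is zero, so
#: that fold changes stay finite; never added to the Fisher table
RATIO_PSEUDOCOUNT = 0.5


class FeatureMismatchError(ValueError):
    """Raised when the two conditions cover different feature universes."""


def rktm(count: float, feature_len_bp: float, library_total: float) -> float:
    """Reads per kilobase of feature per million library reads.

    ``RKTM = count / ((feature_len_bp / 1e3) * (library_total / 1e6))``.
    """
    if feature_len_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / ((feature_len_bp / 1e3) * (library_total / 1e6))


def fisher_exact_2x2(mc_t: int, u_t: int, mc_c: int, u_c: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 methylated/unmethylated table.

    A zero margin (no reads in a condition, or no methylated and no
    unmethylated reads at all) makes the table uninformative: p = 1.
    """
    if min(mc_t, u_t, mc_c, u_c) < 0:
        raise ValueError("counts must be non-negative")
    if (mc_t + u_t == 0) or (mc_c + u_c == 0) or (mc_t + mc_c == 0) or (u_t + u_c == 0):
        logger.debug("degenerate 2x2 margin; p = 1")
        return 1.0
    _, p = stats.fisher_exact([[mc_t, u_t], [mc_c, u_c]], alternative="two-sided")
    return float(p)


def _interval_counts(by_chrom: dict, chrom: str, start: int, end: int):
    """Pooled (mC, total) per context inside [start, end) from sorted arrays."""
    if chrom not in by_chrom:
        return {}
    out = {}
    for ctx, (pos, cmc, ctot) in by_chrom[chrom].items():
        lo, hi = np.searchsorted(pos, start), np.searchsorted(pos, end)
        if hi > lo:
            out[ctx] = (int(cmc[hi] - cmc[lo]), int(ctot[hi] - ctot[lo]))
    return out


def _index_calls(calls: pd.DataFrame) -> dict:
    """chrom -> context -> (sorted pos, cumsum mC, cumsum total)."""
    idx: dict = {}
    for (chrom, ctx), grp in calls.groupby(["chrom", "context"], sort=False):
        g = grp.sort_values("pos")
        pos = g["pos"].to_numpy()
        cmc = np.concatenate([[0], np.cumsum(g["count_methylated"].to_numpy())])
        ctot = np.concatenate([[0], np.cumsum(g["total"].to_numpy())])
        idx.setdefault(chrom, {})[ctx] = (pos, cmc, ctot)
    return idx


def feature_methylation(
    calls: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    library_total: float | None = None,
    regions: Sequence[str] = REGIONS,
    library_mode: str = "methylation_reads",
) -> pd.DataFrame:
    """Pool methylation-supporting reads per gene region and context.

    Parameters
    ----------
    calls
        Per-site table with ``chrom, pos, context, count_methylated,
        total`` (a call table or a raw report with ``total`` added).
    library_total
        Library size for RKTM.  Defaults to the condition's total
        methylation-supporting read count (``library_mode=
        "methylation_reads"``) or total coverage (``"all_reads"``).

    Returns
    -------
    One row per gene x region x context with at least one covered site:
    ``gene, region, context, count_methylated, total, length_bp, rktm,
    ml``.
    """
    if library_total is None:
        if library_mode == "methylation_reads":
            library_total = float(calls["count_methylated"].sum())
        elif library_mode == "all_reads":
            library_total = float(calls["total"].sum())
        else:
            raise ValueError(f"unknown library_mode {library_mode!r}")
        if library_total == 0:
            library_total = 1.0  # empty methylome; RKTM will be all zero
    idx = _index_calls(calls)
    rows = []
    for gm in gene_models:
        for region in regions:
            s, e = gm.region(region)
            if e <= s:
                continue
            for ctx, (mc, tot) in _interval_counts(idx, gm.chrom, s, e).items():
                rows.append(
                    {
                        "gene": gm.gene_id,
                        "region": region,
                        "context": ctx,
                        "count_methylated": mc,
                        "total": tot,
                        "length_bp": e - s,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["gene", "region", "context", "count_methylated", "total", "length_bp"],
    )
    if df.empty:
        df["rktm"] = df["ml"] = np.empty(0)
        return df
    df["rktm_unit"] = 1.0 / ((df["length_bp"] / 1e3) * (library_total / 1e6))
    df["rktm"] = df["count_methylated"] * df["rktm_unit"]
    df["ml"] = df["count_methylated"] / df["total"]
    return df


def _fold_ratio(
    rktm_t: np.ndarray,
    rktm_c: np.ndarray,
    unit_t: np.ndarray,
    unit_c: np.ndarray,
) -> np.ndarray:
    """Symmetric fold change max(t/c, c/t).

    A zero side gets a pseudocount of ``RATIO_PSEUDOCOUNT`` reads (on
    that side's RKTM scale) so the fold change stays finite; the Fisher
    table is never pseudocounted.
    """
    t = np.where(rktm_t == 0, RATIO_PSEUDOCOUNT * unit_t, rktm_t)
    c = np.where(rktm_c == 0, RATIO_PSEUDOCOUNT * unit_c, rktm_c)
    return np.maximum(t / c, c / t)


def call_differential_features(
    features_treatment: pd.DataFrame,
    features_control: pd.DataFrame,
    fdr: float = 0.05,
    fold: float = 2.0,
    keys: Sequence[str] = ("gene", "region", "context"),
) -> pd.DataFrame:
    """Fisher + BH + fold-change differential methylation over features.

    The two inputs are :func:`feature_methylation` tables (or any tables
    with the ``keys`` plus ``count_methylated, total, rktm, ml``).
    Features covered in only one condition are excluded.  BH spans all
    tested features of the run (one family across genes, regions and
    contexts).  ``significant`` requires q < fdr and a fold-change
    (either direction) > fold; ``direction`` is "hyper" when the
    treatment ML exceeds control, else "hypo".
    """
    keys = list(keys)
    t = features_treatment.set_index(keys)
    c = features_control.set_index(keys)
    if t.index.has_duplicates or c.index.has_duplicates:
        raise FeatureMismatchError("duplicate feature keys within a condition")
    common = t.index.intersection(c.index)
    if len(common) == 0:
        raise FeatureMismatchError("no features shared between conditions")
    t = t.loc[common]
    c = c.loc[common]
    mc_t = t["count_methylated"].to_numpy()
    u_t = (t["total"] - t["count_methylated"]).to_numpy()
    mc_c = c["count_methylated"].to_numpy()
    u_c = (c["total"] - c["count_methylated"]).to_numpy()
    p = np.array(
        [fisher_exact_2x2(a, b, d, e) for a, b, d, e in zip(mc_t, u_t, mc_c, u_c)]
    )
    q = benjamini_hochberg(p)
    unit_t = (
        t["rktm_unit"].to_numpy() if "rktm_unit" in t.columns else np.ones(len(t))
    )
    unit_c = (
        c["rktm_unit"].to_numpy() if "rktm_unit" in c.columns else np.ones(len(c))
    )
    ratio = _fold_ratio(t["rktm"].to_numpy(), c["rktm"].to_numpy(), unit_t, unit_c)
    out = pd.DataFrame(index=common).reset_index()
    out["count_methylated_t"] = mc_t
    out["count_methylated_c"] = mc_c
    out["total_t"] = t["total"].to_numpy()
    out["total_c"] = c["total"].to_numpy()
    out["rktm_t"] = t["rktm"].to_numpy()
    out["rktm_c"] = c["rktm"].to_numpy()
    out["ml_t"] = t["ml"].to_numpy()
    out["ml_c"] = c["ml"].to_numpy()
    out["p_value"] = p
    out["q_value"] = q
    out["ratio"] = ratio
    out["direction"] = np.where(out["ml_t"] > out["ml_c"], "hyper", "hypo")
    out["significant"] = (q < fdr) & (ratio > fold)
    return out


def window_methylation(
    calls: pd.DataFrame,
    width: int = 200,
    step: int | None = None,
    library_total: float | None = None,
    library_mode: str = "methylation_reads",
) -> pd.DataFrame:
    """Per-window pooled counts with RKTM, shaped for the differential test."""
    from dmrkit.landscape import sliding_window_levels

    if library_total is None:
        library_total = (
            float(calls["count_methylated"].sum())
            if library_mode == "methylation_reads"
            else float(calls["total"].sum())
        ) or 1.0
    prof = sliding_window_levels(calls, width=width, step=step)
    prof = prof.rename(columns={"start": "window_start", "end": "window_end"})
    prof["rktm_unit"] = 1.0 / ((width / 1e3) * (library_total / 1e6))
    prof["rktm"] = prof["count_methylated"] * prof["rktm_unit"]
    return prof


def call_dmrs(
    windows_treatment: pd.DataFrame,
    windows_control: pd.DataFrame,
    fdr: float = 0.05,
    fold: float = 2.0,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Call and merge differentially methylated regions from window tables.

    Windows (from :func:`window_methylation`, aligned tilings) are
    tested exactly like gene features; significant windows of the same
    chromosome, context and direction are merged when the gap between
    them is <= ``merge_gap`` bp.  Returns BED-style rows ``chrom, start,
    end, context, direction, n_windows, min_q, score`` sorted by
    position (score = -10*log10(min q), capped at 1000).
    """
    diff = call_differential_features(
        windows_treatment,
        windows_control,
        fdr=fdr,
        fold=fold,
        keys=("chrom", "window_start", "window_end", "context"),
    )
    sig = diff[diff["significant"]].sort_values(["chrom", "context", "direction", "window_start"])
    merged_rows = []
    for (chrom, ctx, direction), grp in sig.groupby(
        ["chrom", "context", "direction"], sort=False
    ):
        cur_start = cur_end = None
        qs: list[float] = []
        n = 0
        for _, row in grp.iterrows():
            s, e = int(row["window_start"]), int(row["window_end"])
            if cur_start is None:
                cur_start, cur_end, qs, n = s, e, [row["q_value"]], 1
            elif s - cur_end <= merge_gap:
                cur_end = max(cur_end, e)
                qs.append(row["q_value"])
                n += 1
            else:
                merged_rows.append((chrom, cur_start, cur_end, ctx, direction, n, min(qs)))
                cur_start, cur_end, qs, n = s, e, [row["q_value"]], 1
        if cur_start is not None:
            merged_rows.append((chrom, cur_start, cur_end, ctx, direction, n, min(qs)))
    out = pd.DataFrame(
        merged_rows,
        columns=["chrom", "start", "end", "context", "direction", "n_windows", "min_q"],
    )
    if len(out):
        with np.errstate(divide="ignore"):
            out["score"] = np.minimum(1000.0, -10.0 * np.log10(out["min_q"]))
    else:
        out["score"] = np.empty(0)
    return out.sort_values(["chrom", "start", "end", "context"]).reset_index(drop=True)


def summarize_dmgs(diff: pd.DataFrame) -> pd.DataFrame:
    """Collapse region-resolved differential calls to one row per gene.

    A gene may be hypermethylated in one region and hypomethylated in
    another; both labels are retained.  ``classification`` is "hyper" or
    "hypo" when all affected regions agree, "mixed" otherwise.

    Returns columns ``gene, regions, n_regions, hyper_regions,
    hypo_regions, classification``.
    """
    sig = diff[diff["significant"]]
    rows = []
    for gene, grp in sig.groupby("gene", sort=True):
        hyper = sorted(set(grp.loc[grp["direction"] == "hyper", "region"]))
        hypo = sorted(set(grp.loc[grp["direction"] == "hypo", "region"]))
        regions = sorted(set(grp["region"]))
        if hyper and hypo:
            cls = "mixed"
        elif hyper:
            cls = "hyper"
        else:
            cls = "hypo"
        rows.append(
            {
                "gene": gene,
                "regions": ",".join(regions),
                "n_regions": len(regions),
                "hyper_regions": ",".join(hyper),
                "hypo_regions": ",".join(hypo),
                "classification": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "regions", "n_regions", "hyper_regions", "hypo_regions", "classification"],
    )


def region_direction_overlap(diff: pd.DataFrame) -> pd.DataFrame:
    """Gene membership matrix per region x direction for overlap counting.

    One row per gene with boolean columns ``<region>_<direction>`` --
    the raw material for Venn-style summaries of which regions of a gene
    gained or lost methylation.
    """
    sig = diff[diff["significant"]]
    genes = sorted(set(sig["gene"]))
    out = pd.DataFrame({"gene": genes}).set_index("gene")
    for region in REGIONS:
        for direction in ("hyper", "hypo"):
            members = set(
                sig.loc[(sig["region"] == region) & (sig["direction"] == direction), "gene"]
            )
            out[f"{region}_{direction}"] = [g in members for g in genes]
    return out.reset_index()
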