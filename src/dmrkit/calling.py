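"""Methylcytosine calling.

Bisulfite treatment converts unmethylated cytosines to uracil (read as
T) while 5-methylcytosine is protected.  A site covered by ``n`` reads
of which ``k`` report C is tested against the null that all C readouts
arise from incomplete conversion at rate epsilon, with the one-sided
exact binomial p-value ``P[X >= k | n, epsilon]``.  Calls are made at a
genome-wide Benjamini-Hochberg FDR (default 1%).  The methylation level
of a site or pooled region is ML = mC / (mC + non-mC), the fraction of
read observations supporting methylation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: lower floor for the estimated non-conversion rate; a control set with
#: zero non-converted reads would otherwise give degenerate p-values
EPSILON_FLOOR = 1e-4


class CoverageError(ValueError):
    """Raised when a control set has zero total coverage."""


def estimate_nonconversion(
    count_methylated: Sequence[int] | np.ndarray,
    count_unmethylated: Sequence[int] | np.ndarray,
    floor: float = EPSILON_FLOOR,
) -> float:
    """Estimate the bisulfite non-conversion rate epsilon.

    Pools read counts over a set of sites known (or assumed) to be
    unmethylated -- simulator truth, spike-in, or organellar DNA -- and
    returns the pooled fraction of reads still reporting C.

    Raises :class:`CoverageError` if total coverage is zero.  A pooled
    estimate of exactly zero is floored to ``floor`` (logged).
    """
    m = int(np.sum(count_methylated))
    u = int(np.sum(count_unmethylated))
    total = m + u
    if total == 0:
        raise CoverageError("control site set has zero total coverage")
    eps = m / total
    if eps == 0.0:
        logger.info("observed non-conversion 0/%d; flooring epsilon to %g", total, floor)
        eps = floor
    return eps


def binomial_site_test(
    count_methylated: int | np.ndarray,
    total: int | np.ndarray,
    epsilon: float,
) -> float | np.ndarray:
    """One-sided upper-tail exact binomial p-value.

    ``P[X >= k | n = total, p = epsilon]`` -- the probability of seeing
    at least the observed number of unconverted reads if the site were
    fully unmethylated.  Vectorised over arrays.  ``total`` must be >= 1;
    uncovered sites carry no p-value and must be excluded upstream.
    """
    k = np.asarray(count_methylated)
    n = np.asarray(total)
    if np.any(n < 1):
        raise ValueError("binomial_site_test requires total >= 1 (exclude uncovered sites)")
    p = stats.binom.sf(k - 1, n, epsilon)
    if np.isscalar(count_methylated) and np.isscalar(total):
        return float(p)
    return p


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone, ties preserved, output order matches input order.  Empty
    input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_methylome(
    pileups: pd.DataFrame,
    epsilon: float,
    fdr: float = 0.01,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Call methylated cytosines for one condition.

    Parameters
    ----------
    pileups
        Cytosine report for one condition: columns ``chrom, pos, strand,
        context, count_methylated, count_unmethylated``.
    epsilon
        Non-conversion rate (see :func:`estimate_nonconversion`).
    fdr
        Genome-wide BH FDR threshold for the methylated call.
    min_coverage
        Sites with fewer total reads are excluded from testing entirely.

    Returns
    -------
    DataFrame of tested sites with added columns ``total, ml, p_value,
    q_value, is_methylated``.  BH is applied jointly over all tested
    sites of the condition (all contexts, one family).  ML is reported
    for every tested site regardless of the call.
    """
    df = pileups.copy()
    df["total"] = df["count_methylated"] + df["count_unmethylated"]
    df = df[df["total"] >= max(1, min_coverage)].reset_index(drop=True)
    if df.empty:
        df["ml"] = df["p_value"] = df["q_value"] = np.empty(0)
        df["is_methylated"] = np.empty(0, dtype=bool)
        return df
    frac = df["count_methylated"].to_numpy() / df["total"].to_numpy()
    if epsilon >= frac.max():
        logger.warning(
            "epsilon %.4g >= max observed methylated fraction %.4g; no site can be called",
            epsilon,
            frac.max(),
        )
    df["ml"] = frac
    df["p_value"] = binomial_site_test(
        df["count_methylated"].to_numpy(), df["total"].to_numpy(), epsilon
    )
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["is_methylated"] = df["q_value"] <= fdr
    return df


def pool_cg_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Pool the two strands of each symmetric CG dinucleotide.

    A CG on the forward strand at position p pairs with the CG on the
    reverse strand at p+1.  Counts are summed; the pooled ML equals the
    count-weighted combination of the per-strand MLs by construction.
    Non-CG sites are returned unchanged.
    """
    cg = calls[calls["context"] == "CG"].copy()
    other = calls[calls["context"] != "CG"]
    # anchor both strands of a CG pair at the forward-strand C position
    anchor = cg["pos"].where(cg["strand"] == "+", cg["pos"] - 1)
    cg["_anchor"] = anchor
    grouped = (
        cg.groupby(["chrom", "_anchor"], as_index=False)
        .agg(
            count_methylated=("count_methylated", "sum"),
            count_unmethylated=("count_unmethylated", "sum"),
        )
        .rename(columns={"_anchor": "pos"})
    )
    grouped["strand"] = "+"
    grouped["context"] = "CG"
    grouped["total"] = grouped["count_methylated"] + grouped["count_unmethylated"]
    grouped["ml"] = grouped["count_methylated"] / grouped["total"]
    cols = ["chrom", "pos", "strand", "context", "count_methylated", "count_unmethylated", "total", "ml"]
    out = pd.concat([grouped[cols], other.reindex(columns=cols)], ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
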