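"""No-replicate differential expression and methylation-expression integration.

Two unreplicated RNA-seq libraries are compared per gene with the
Audic-Claverie exact test: conditioned on the control count ``x`` and
the library-size ratio, the treatment count under the null follows the
posterior-predictive distribution

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

which is a negative binomial with ``r = x + 1`` successes and success
probability ``N1/(N1+N2)``.  The two-sided p-value is twice the smaller
tail, capped at 1; because the construction is not symmetric in the two
libraries, the test averages the p-values of both orientations so that
swapping (count, library) pairs leaves p unchanged.

Genes pass the differential-expression filter at FDR <= 0.001 and
|log2 ratio| >= 1 (library-size-normalised counts, pseudocount 1).  The
joint methylation-expression filter retains gene x region pairs that
are differentially methylated at raw p < 0.05 with a >= 2-fold RKTM
ratio *and* differentially expressed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dmrkit.calling import benjamini_hochberg
from dmrkit.genome import REGIONS

logger = logging.getLogger(__name__)


def _ac_two_sided(x: int, y: int, lib_x: float, lib_y: float) -> float:
    """2*min(tails) of y given x under the scaled negative-binomial null."""
    pr = lib_x / (lib_x + lib_y)
    upper = stats.nbinom.sf(y - 1, x + 1, pr)
    lower = stats.nbinom.cdf(y, x + 1, pr)
    return min(1.0, 2.0 * min(upper, lower))


def audic_claverie_test(
    count_a: int, count_b: int, lib_a: float, lib_b: float
) -> float:
    """Symmetrised Audic-Claverie exact p-value for two unreplicated libraries.

    Averages the two-sided p of ``b given a`` and ``a given b`` so the
    result is invariant under swapping the libraries.  Genes with zero
    counts in both libraries carry no evidence and must be excluded
    upstream (raises ValueError).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a == 0 and count_b == 0:
        raise ValueError("gene with zero counts in both libraries: no test")
    p1 = _ac_two_sided(count_a, count_b, lib_a, lib_b)
    p2 = _ac_two_sided(count_b, count_a, lib_b, lib_a)
    return min(1.0, 0.5 * (p1 + p2))


def call_de(
    table: pd.DataFrame,
    fdr: float = 0.001,
    min_log2fc: float = 1.0,
    lib_ck: float | None = None,
    lib_atr: float | None = None,
) -> pd.DataFrame:
    """Flag differentially expressed genes between two libraries.

    Parameters
    ----------
    table
        Columns ``gene, count_ck, count_atr``.
    lib_ck, lib_atr
        Library sizes; default to the column totals.

    Returns
    -------
    Per-gene table with ``norm_ck, norm_atr`` (counts per million),
    ``log2fc`` (treatment over control, pseudocount 1 before
    normalisation), ``p_value, q_value, significant, direction``.
    Genes with zero counts in both libraries are dropped.
    """
    df = table.copy()
    lib_ck = float(df["count_ck"].sum()) if lib_ck is None else float(lib_ck)
    lib_atr = float(df["count_atr"].sum()) if lib_atr is None else float(lib_atr)
    df = df[(df["count_ck"] + df["count_atr"]) > 0].reset_index(drop=True)
    if df.empty:
        for col in ("norm_ck", "norm_atr", "log2fc", "p_value", "q_value"):
            df[col] = np.empty(0)
        df["significant"] = np.empty(0, dtype=bool)
        df["direction"] = np.empty(0, dtype=object)
        return df
    df["norm_ck"] = df["count_ck"] / lib_ck * 1e6
    df["norm_atr"] = df["count_atr"] / lib_atr * 1e6
    df["log2fc"] = np.log2(
        ((df["count_atr"] + 1) / lib_atr) / ((df["count_ck"] + 1) / lib_ck)
    )
    df["p_value"] = [
        audic_claverie_test(a, b, lib_ck, lib_atr)
        for a, b in zip(df["count_ck"], df["count_atr"])
    ]
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = (df["q_value"] <= fdr) & (df["log2fc"].abs() >= min_log2fc)
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df


def joint_filter(
    diff_meth: pd.DataFrame,
    de: pd.DataFrame,
    p_meth: float = 0.05,
    fold_meth: float = 2.0,
) -> pd.DataFrame:
    """Joint methylation-expression filter.

    Retains gene x region (x context) rows from ``diff_meth`` (a
    :func:`dmrkit.differential.call_differential_features` table) where
    the methylation change passes raw ``p < p_meth`` with fold ratio
    ``>= fold_meth``, and the gene is flagged significant in ``de``.
    Note the methylation side deliberately uses the *unadjusted* p-value
    here -- a looser screen than the FDR-based DMG caller; both numbers
    are part of the pipeline summary.

    Returns one row per passing gene x region with ``quadrant`` labels
    like ``upstream-hyper/expr-down``.
    """
    de_sig = de[de["significant"]][["gene", "log2fc", "direction"]].rename(
        columns={"direction": "expr_direction"}
    )
    meth = diff_meth[
        (diff_meth["p_value"] < p_meth) & (diff_meth["ratio"] >= fold_meth)
    ].copy()
    merged = meth.merge(de_sig, on="gene", how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=list(meth.columns) + ["log2fc", "expr_direction", "quadrant"]
        )
    merged["quadrant"] = (
        merged["region"]
        + "-"
        + merged["direction"]
        + "/expr-"
        + merged["expr_direction"]
    )
    return merged.reset_index(drop=True)


def joint_region_counts(joint: pd.DataFrame) -> pd.DataFrame:
    """Counts of joint-filter genes per region x methylation direction.

    One gene is counted once per region (contexts collapsed).
    """
    rows = []
    for region in REGIONS:
        for direction in ("hyper", "hypo"):
            sub = joint[(joint["region"] == region) & (joint["direction"] == direction)]
            rows.append(
                {"region": region, "direction": direction, "n_genes": sub["gene"].nunique()}
            )
    return pd.DataFrame(rows)


def association_summary(
    diff_meth: pd.DataFrame,
    de: pd.DataFrame,
    gene_classes: Mapping[str, str] | None = None,
    regions: Sequence[str] = REGIONS,
) -> pd.DataFrame:
    """Methylation-change vs expression-change association per region.

    For every region (and gene class: "all" plus any labels supplied in
    ``gene_classes``, unknown labels grouped as "other"), computes the
    Spearman rank correlation between the methylation log2 RKTM ratio
    and the expression log2 fold change over genes covered in both
    tables, plus quadrant counts (methylation up/down x expression
    up/down).  Quadrant counts sum to the number of genes analysed in
    the panel.
    """
    meth = diff_meth.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        unit_t = meth["rktm_unit"] if "rktm_unit" in meth.columns else 1.0
        t = np.where(meth["rktm_t"] > 0, meth["rktm_t"], 0.5 * unit_t)
        c = np.where(meth["rktm_c"] > 0, meth["rktm_c"], 0.5 * unit_t)
        meth["meth_log2_ratio"] = np.log2(t / c)
    # collapse contexts: keep the context with the smallest p per gene x region
    meth = meth.sort_values("p_value").drop_duplicates(["gene", "region"])
    expr = de[["gene", "log2fc"]]
    merged = meth.merge(expr, on="gene", how="inner")
    if gene_classes:
        known = set(gene_classes.values())
        merged["gene_class"] = [
            gene_classes.get(g, "other") for g in merged["gene"]
        ]
    else:
        merged["gene_class"] = "all"
    rows = []
    class_values = ["all"] + (sorted(set(merged["gene_class"])) if gene_classes else [])
    for region in regions:
        panel_all = merged[merged["region"] == region]
        for cls in class_values:
            panel = panel_all if cls == "all" else panel_all[panel_all["gene_class"] == cls]
            n = len(panel)
            if n >= 3:
                rho, pval = stats.spearmanr(
                    panel["meth_log2_ratio"], panel["log2fc"]
                )
            else:
                rho, pval = np.nan, np.nan
            quad = {
                "n_meth_up_expr_up": int(((panel["meth_log2_ratio"] > 0) & (panel["log2fc"] > 0)).sum()),
                "n_meth_up_expr_down": int(((panel["meth_log2_ratio"] > 0) & (panel["log2fc"] <= 0)).sum()),
                "n_meth_down_expr_up": int(((panel["meth_log2_ratio"] <= 0) & (panel["log2fc"] > 0)).sum()),
                "n_meth_down_expr_down": int(((panel["meth_log2_ratio"] <= 0) & (panel["log2fc"] <= 0)).sum()),
            }
            rows.append(
                {"region": region, "gene_class": cls, "n_genes": n, "spearman_rho": rho, "spearman_p": pval, **quad}
            )
    return pd.DataFrame(rows)
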