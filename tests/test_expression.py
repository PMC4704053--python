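"""No-replicate differential expression and methylation-expression integration."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrkit.expression import (
    association_summary,
    audic_claverie_test,
    call_de,
    joint_filter,
    joint_region_counts,
)


def ac_oracle(x, y, lib_x, lib_y, nmax=4000):
    """Brute-force Audic-Claverie p: direct summation of the posterior
    predictive pmf (in logs), two-sided 2*min(tails), symmetrised by
    averaging the two orientations."""

    def pmf_log(yy, xx, r):
        # log P(y|x) = y*log r + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
        #              - (x+y+1)*log(1+r),   r = N2/N1
        return (
            yy * math.log(r)
            + math.lgamma(xx + yy + 1)
            - math.lgamma(xx + 1)
            - math.lgamma(yy + 1)
            - (xx + yy + 1) * math.log1p(r)
        )

    def two_sided(xx, yy, n1, n2):
        r = n2 / n1
        probs = [math.exp(pmf_log(j, xx, r)) for j in range(nmax)]
        upper = sum(probs[yy:])
        lower = sum(probs[: yy + 1])
        return min(1.0, 2.0 * min(upper, lower))

    return min(1.0, 0.5 * (two_sided(x, y, lib_x, lib_y) + two_sided(y, x, lib_y, lib_x)))


def test_equal_counts_equal_libs_near_one():
    assert audic_claverie_test(10, 10, 1e6, 1e6) > 0.9
    assert audic_claverie_test(100, 100, 1e6, 1e6) > 0.9


def test_ac_matches_brute_force_example():
    got = audic_claverie_test(0, 20, 1e6, 1e6)
    want = ac_oracle(0, 20, 1e6, 1e6)
    assert got == pytest.approx(want, rel=1e-9)
    assert got < 1e-4


@pytest.mark.parametrize(
    "x,y,lx,ly",
    [(0, 20, 1e6, 1e6), (5, 30, 1e6, 2e6), (12, 3, 5e5, 1e6), (7, 7, 1e6, 3e6)],
)
def test_ac_oracle_equivalence(x, y, lx, ly):
    assert audic_claverie_test(x, y, lx, ly) == pytest.approx(
        ac_oracle(x, y, lx, ly), rel=1e-8
    )


def test_ac_swap_invariance():
    rng = np.random.default_rng(17)
    for _ in range(50):
        x, y = int(rng.integers(0, 100)), int(rng.integers(0, 100))
        if x == y == 0:
            continue
        lx, ly = float(rng.integers(1, 5) * 1e5), float(rng.integers(1, 5) * 1e5)
        assert audic_claverie_test(x, y, lx, ly) == pytest.approx(
            audic_claverie_test(y, x, ly, lx), rel=1e-12
        )


def test_ac_rejects_double_zero():
    with pytest.raises(ValueError):
        audic_claverie_test(0, 0, 1e6, 1e6)


def test_call_de_null_calibration():
    rng = np.random.default_rng(23)
    mu = rng.lognormal(5, 1, size=2000)
    table = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(2000)], "count_ck": rng.poisson(mu), "count_atr": rng.poisson(mu)}
    )
    de = call_de(table, fdr=0.001, min_log2fc=1.0)
    # under the null essentially nothing should pass the joint threshold
    assert de["significant"].mean() <= 0.001 + 3 * np.sqrt(0.001 / len(de))


def test_call_de_recovers_strong_down_regulation():
    rng = np.random.default_rng(29)
    mu = rng.lognormal(5, 1, size=500)
    ck = rng.poisson(mu)
    atr = rng.poisson(mu)
    ck[0], atr[0] = 4000, 1000  # true log2FC = -2 at high expression
    table = pd.DataFrame({"gene": [f"g{i}" for i in range(500)], "count_ck": ck, "count_atr": atr})
    de = call_de(table).set_index("gene")
    assert bool(de.loc["g0", "significant"])
    assert de.loc["g0", "direction"] == "down"
    assert de.loc["g0", "log2fc"] == pytest.approx(-2.0, abs=0.3)


def test_call_de_log2fc_threshold_boundary():
    # huge counts => tiny p, but |log2FC| < 1 must not be flagged
    lib = 1_000_000
    a = 100_000
    b = int(a * 2**0.99)
    table = pd.DataFrame({"gene": ["g"], "count_ck": [a], "count_atr": [b]})
    de = call_de(table, lib_ck=lib, lib_atr=lib)
    assert de["p_value"].iloc[0] < 1e-10
    assert abs(de["log2fc"].iloc[0]) < 1.0
    assert not de["significant"].iloc[0]


def _meth_table(rows):
    df = pd.DataFrame(
        rows,
        columns=["gene", "region", "context", "p_value", "ratio", "direction", "ml_t", "ml_c"],
    )
    df["rktm_t"] = np.where(df["direction"] == "hyper", df["ratio"], 1.0)
    df["rktm_c"] = np.where(df["direction"] == "hyper", 1.0, df["ratio"])
    df["rktm_unit"] = 1.0
    df["q_value"] = df["p_value"]
    df["significant"] = (df["p_value"] < 0.05) & (df["ratio"] > 2)
    return df


def _de_table(sig_genes, all_genes, lfc=-2.0):
    df = pd.DataFrame({"gene": all_genes})
    df["log2fc"] = np.where(df["gene"].isin(sig_genes), lfc, 0.1)
    df["significant"] = df["gene"].isin(sig_genes)
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df


def test_joint_filter_empty_de_set():
    meth = _meth_table([("g1", "upstream", "CG", 0.001, 5.0, "hyper", 0.8, 0.2)])
    de = _de_table([], ["g1"])
    assert joint_filter(meth, de).empty


def test_joint_filter_single_passing_gene_quadrant():
    meth = _meth_table(
        [
            ("g1", "upstream", "CG", 0.001, 5.0, "hyper", 0.8, 0.2),
            ("g2", "upstream", "CG", 0.5, 5.0, "hyper", 0.5, 0.4),  # fails p
            ("g3", "upstream", "CG", 0.001, 1.5, "hyper", 0.5, 0.4),  # fails fold
        ]
    )
    de = _de_table(["g1", "g2", "g3"], ["g1", "g2", "g3"])
    joint = joint_filter(meth, de)
    assert list(joint["gene"]) == ["g1"]
    assert joint["quadrant"].iloc[0] == "upstream-hyper/expr-down"


def test_joint_filter_is_subset_of_both_inputs():
    rng = np.random.default_rng(31)
    genes = [f"g{i}" for i in range(20)]
    meth_rows = [
        (
            g,
            rng.choice(["upstream", "genebody", "downstream"]),
            "CG",
            float(rng.choice([0.001, 0.2])),
            float(rng.choice([1.2, 4.0])),
            str(rng.choice(["hyper", "hypo"])),
            0.6,
            0.3,
        )
        for g in genes
    ]
    meth = _meth_table(meth_rows)
    de_sig = [g for g in genes if rng.random() < 0.4]
    de = _de_table(de_sig, genes)
    joint = joint_filter(meth, de)
    meth_pass = set(meth.loc[(meth["p_value"] < 0.05) & (meth["ratio"] >= 2), "gene"])
    assert set(joint["gene"]).issubset(meth_pass & set(de_sig))
    # brute-force region x direction counts
    counts = joint_region_counts(joint).set_index(["region", "direction"])
    for region in ("upstream", "genebody", "downstream"):
        for direction in ("hyper", "hypo"):
            expected = joint[(joint["region"] == region) & (joint["direction"] == direction)]["gene"].nunique()
            assert counts.loc[(region, direction), "n_genes"] == expected


def test_association_quadrant_counts_sum_to_panel_size():
    meth = _meth_table(
        [
            (f"g{i}", "upstream", "CG", 0.01, 3.0, "hyper" if i % 2 else "hypo", 0.6, 0.3)
            for i in range(12)
        ]
    )
    de = _de_table([f"g{i}" for i in range(4)], [f"g{i}" for i in range(12)])
    assoc = association_summary(meth, de).set_index(["region", "gene_class"])
    row = assoc.loc[("upstream", "all")]
    total = (
        row["n_meth_up_expr_up"]
        + row["n_meth_up_expr_down"]
        + row["n_meth_down_expr_up"]
        + row["n_meth_down_expr_down"]
    )
    assert total == row["n_genes"] == 12


def test_association_null_coupling_near_zero():
    rng = np.random.default_rng(37)
    n = 300
    meth = _meth_table(
        [
            (
                f"g{i}",
                "upstream",
                "CG",
                0.5,
                float(np.exp2(abs(rng.normal(0, 0.5)))),
                str(rng.choice(["hyper", "hypo"])),
                0.5,
                0.5,
            )
            for i in range(n)
        ]
    )
    de = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n)],
            "log2fc": rng.normal(0, 1, n),
            "significant": False,
            "direction": "up",
        }
    )
    assoc = association_summary(meth, de).set_index(["region", "gene_class"])
    rho = assoc.loc[("upstream", "all"), "spearman_rho"]
    assert abs(rho) < 0.15


def test_association_unknown_class_grouped_as_other():
    meth = _meth_table([("g1", "upstream", "CG", 0.01, 3.0, "hyper", 0.6, 0.3)] )
    de = _de_table(["g1"], ["g1"])
    assoc = association_summary(meth, de, gene_classes={"gX": "TF"})
    assert "other" in set(assoc["gene_class"])
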