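"""Differential methylation: RKTM, Fisher, feature calls, DMRs, DMG summary."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dmrkit.differential import (
    call_differential_features,
    call_dmrs,
    fisher_exact_2x2,
    region_direction_overlap,
    rktm,
    summarize_dmgs,
    window_methylation,
)


def fisher_oracle(a, b, c, d):
    """Enumerate all 2x2 tables with the observed margins; two-sided p is
    the total probability of tables no more likely than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    p_obs = hyper(a)
    return sum(p for x in range(lo, hi + 1) if (p := hyper(x)) <= p_obs * (1 + 1e-7))


def test_rktm_unit_case():
    assert rktm(100, 1000, 1_000_000) == pytest.approx(100.0)


def test_rktm_zero_count():
    assert rktm(0, 1000, 1e6) == 0.0


def test_rktm_arithmetic():
    assert rktm(50, 500, 2_000_000) == pytest.approx(50.0)


@pytest.mark.parametrize("len_bp,lib", [(0, 1e6), (1000, 0)])
def test_rktm_rejects_degenerate_denominators(len_bp, lib):
    with pytest.raises(ValueError):
        rktm(10, len_bp, lib)


def test_fisher_identical_proportions():
    assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_extreme_table_closed_form():
    assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / math.comb(20, 10), rel=1e-9)


def test_fisher_zero_margin_convention():
    assert fisher_exact_2x2(0, 0, 5, 5) == 1.0
    assert fisher_exact_2x2(0, 3, 0, 5) == 1.0


@settings(derandomize=True, max_examples=300, deadline=None)
@given(st.tuples(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)))
def test_fisher_oracle_equivalence(table):
    a, b, c, d = table
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        assert fisher_exact_2x2(a, b, c, d) == 1.0
    else:
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-6
        )


def _feature_table(rows):
    df = pd.DataFrame(
        rows, columns=["gene", "region", "context", "count_methylated", "total"]
    )
    df["length_bp"] = 1000
    lib = max(1.0, float(df["count_methylated"].sum()))
    df["rktm_unit"] = 1.0 / ((df["length_bp"] / 1e3) * (lib / 1e6))
    df["rktm"] = df["count_methylated"] * df["rktm_unit"]
    df["ml"] = df["count_methylated"] / df["total"]
    return df


def test_identical_conditions_yield_no_calls():
    rows = [(f"g{i}", "upstream", "CG", 10 + i, 40) for i in range(20)]
    f = _feature_table(rows)
    diff = call_differential_features(f, f.copy())
    assert not diff["significant"].any()
    assert (diff["p_value"] == 1.0).all()


def test_condition_swap_flips_direction_keeps_p():
    rng = np.random.default_rng(3)
    rows_t = [(f"g{i}", "upstream", "CG", int(rng.integers(0, 50)), 100) for i in range(30)]
    rows_c = [(f"g{i}", "upstream", "CG", int(rng.integers(0, 50)), 100) for i in range(30)]
    ft, fc = _feature_table(rows_t), _feature_table(rows_c)
    d1 = call_differential_features(ft, fc).set_index("gene")
    d2 = call_differential_features(fc, ft).set_index("gene")
    assert d1["p_value"].to_dict() == pytest.approx(d2["p_value"].to_dict())
    both = d1.join(d2, lsuffix="_1", rsuffix="_2")
    changed = both[both["ml_t_1"] != both["ml_c_1"]]
    assert (
        (changed["direction_1"] == "hyper") == (changed["direction_2"] == "hypo")
    ).all()


def test_direction_matches_ml_sign(small_features):
    f_atr, f_ck = small_features
    diff = call_differential_features(f_atr, f_ck)
    sig = diff[diff["significant"]]
    assert ((sig["ml_t"] > sig["ml_c"]) == (sig["direction"] == "hyper")).all()


def test_significance_requires_fold_and_fdr(small_features):
    f_atr, f_ck = small_features
    diff = call_differential_features(f_atr, f_ck, fdr=0.05, fold=2.0)
    sig = diff[diff["significant"]]
    assert (sig["q_value"] < 0.05).all()
    assert (sig["ratio"] > 2.0).all()
    # an unreachable fold threshold silences every call
    none = call_differential_features(f_atr, f_ck, fold=1e12)
    assert not none["significant"].any()


def _window_table(sig_flags, width=200, base=(5, 100), alt=(80, 100)):
    """Build aligned window tables where flagged windows differ strongly."""
    rows_t, rows_c = [], []
    for i, flag in enumerate(sig_flags):
        s = i * width
        mc_c, tot = base
        mc_t = alt[0] if flag else base[0]
        rows_t.append(("c", s, s + width, "CG", mc_t, tot))
        rows_c.append(("c", s, s + width, "CG", mc_c, tot))

    def mk(rows):
        df = pd.DataFrame(
            rows,
            columns=["chrom", "window_start", "window_end", "context", "count_methylated", "total"],
        )
        df["ml"] = df["count_methylated"] / df["total"]
        # common library size so the fixture's fold changes are the
        # plain count ratios
        df["rktm_unit"] = 1.0 / ((width / 1e3) * (1e6 / 1e6))
        df["rktm"] = df["count_methylated"] * df["rktm_unit"]
        return df

    return mk(rows_t), mk(rows_c)


def test_dmrs_empty_when_nothing_significant():
    wt, wc = _window_table([False] * 10)
    assert call_dmrs(wt, wc).empty


def test_adjacent_significant_windows_merge():
    wt, wc = _window_table([False, True, True, False])
    dmrs = call_dmrs(wt, wc, merge_gap=0)
    assert len(dmrs) == 1
    row = dmrs.iloc[0]
    assert (row["start"], row["end"]) == (200, 600)
    assert row["n_windows"] == 2
    assert row["direction"] == "hyper"


def test_dmr_merge_matches_brute_force_on_window_fixture():
    flags = [False, True, True, False, True, False, False, True, True, True,
             False, True, False, False, True, True, False, False, False, True]
    wt, wc = _window_table(flags)
    dmrs = call_dmrs(wt, wc, merge_gap=0)
    # brute-force merge of runs of consecutive flagged windows
    expected = []
    run = None
    for i, f in enumerate(flags + [False]):
        if f and run is None:
            run = i
        elif not f and run is not None:
            expected.append((run * 200, i * 200))
            run = None
    assert [(r["start"], r["end"]) for _, r in dmrs.iterrows()] == expected


def test_dmr_merge_gap_bridges_single_hole():
    flags = [True, False, True]
    wt, wc = _window_table(flags)
    assert len(call_dmrs(wt, wc, merge_gap=0)) == 2
    assert len(call_dmrs(wt, wc, merge_gap=200)) == 1


def _diff_fixture():
    rows = [
        # gene, region, context, sig, direction
        ("g1", "upstream", "CG", True, "hyper"),
        ("g2", "upstream", "CG", True, "hyper"),
        ("g2", "genebody", "CG", True, "hypo"),
        ("g3", "genebody", "CHG", True, "hypo"),
        ("g4", "downstream", "CHH", False, "hyper"),
    ]
    return pd.DataFrame(
        [
            {
                "gene": g,
                "region": r,
                "context": c,
                "significant": s,
                "direction": d,
            }
            for g, r, c, s, d in rows
        ]
    )


def test_dmg_summary_single_region_gene():
    dmg = summarize_dmgs(_diff_fixture()).set_index("gene")
    assert dmg.loc["g1", "classification"] == "hyper"
    assert dmg.loc["g1", "regions"] == "upstream"


def test_dmg_summary_keeps_mixed_directions():
    dmg = summarize_dmgs(_diff_fixture()).set_index("gene")
    assert dmg.loc["g2", "classification"] == "mixed"
    assert dmg.loc["g2", "hyper_regions"] == "upstream"
    assert dmg.loc["g2", "hypo_regions"] == "genebody"
    assert "g4" not in dmg.index  # non-significant genes excluded


def test_region_overlap_counts_match_set_algebra():
    rng = np.random.default_rng(9)
    rows = []
    for i in range(10):
        for region in ("upstream", "genebody", "downstream"):
            rows.append(
                {
                    "gene": f"g{i}",
                    "region": region,
                    "context": "CG",
                    "significant": bool(rng.random() < 0.5),
                    "direction": "hyper" if rng.random() < 0.5 else "hypo",
                }
            )
    diff = pd.DataFrame(rows)
    overlap = region_direction_overlap(diff).set_index("gene")
    sig = diff[diff["significant"]]
    up_hyper = set(sig[(sig["region"] == "upstream") & (sig["direction"] == "hyper")]["gene"])
    gb_hyper = set(sig[(sig["region"] == "genebody") & (sig["direction"] == "hyper")]["gene"])
    both = {g for g in overlap.index if overlap.loc[g, "upstream_hyper"] and overlap.loc[g, "genebody_hyper"]}
    assert both == (up_hyper & gb_hyper)
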