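import numpy as np
import pandas as pd
import pytest

import dmrkit as dk
from dmrkit.simulate import MethylomeModel, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 chromosomes x 10 genes, default methylome preset, fixed seed."""
    return simulate_dataset(seed=7, genes_per_chrom=10)


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    ds = small_dataset
    eps = ds.model.nonconversion
    calls_ck = dk.call_methylome(ds.report_ck, eps)
    calls_atr = dk.call_methylome(ds.report_atr, eps)
    return calls_ck, calls_atr


@pytest.fixture(scope="session")
def small_features(small_dataset, small_calls):
    from dmrkit.differential import feature_methylation

    ds = small_dataset
    calls_ck, calls_atr = small_calls
    f_ck = feature_methylation(calls_ck, ds.gene_models)
    f_atr = feature_methylation(calls_atr, ds.gene_models)
    return f_atr, f_ck


def make_calls_frame(rows):
    """Helper: build a per-site call-style table from (chrom,pos,strand,ctx,mc,u)."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_methylated", "count_unmethylated"]
    )
    df["total"] = df["count_methylated"] + df["count_unmethylated"]
    df["ml"] = df["count_methylated"] / df["total"]
    return df
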