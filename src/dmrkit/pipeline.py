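"""End-to-end orchestration from cytosine reports to final tables.

Stages: methylcytosine calling per condition -> landscape summaries ->
differential methylation over gene regions and windows (DMRs/DMGs) ->
no-replicate differential expression and the joint filter -> miRNA
locus ratios -> JSON summary of headline counts.  Outputs are
deterministic for fixed inputs: all tables are written sorted with a
fixed float format, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dmrkit import io as dio
from dmrkit.calling import call_methylome, estimate_nonconversion
from dmrkit.config import RunConfig
from dmrkit.differential import (
    call_differential_features,
    call_dmrs,
    feature_methylation,
    region_direction_overlap,
    summarize_dmgs,
    window_methylation,
)
from dmrkit.expression import (
    association_summary,
    call_de,
    joint_filter,
    joint_region_counts,
)
from dmrkit.genome import build_gene_models, read_fasta
from dmrkit.landscape import (
    chromosome_profile,
    context_composition,
    feature_metaprofile,
    sliding_window_levels,
)
from dmrkit.mirna import compare_locus_methylation, locus_methylation, two_fold_filter

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    calls_ck: pd.DataFrame
    calls_atr: pd.DataFrame
    diff_features: pd.DataFrame
    dmrs: pd.DataFrame
    dmg_summary: pd.DataFrame
    de: pd.DataFrame
    joint: pd.DataFrame
    association: pd.DataFrame
    mirna: pd.DataFrame | None
    summary: dict


def _write(df: pd.DataFrame, path: Path, sort_by=None) -> None:
    out = df.sort_values(sort_by).reset_index(drop=True) if sort_by else df
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    (out / "FAILED_STAGE").write_text(name + "\n")
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    with stage("load"):
        genome = read_fasta(config.genome)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        gene_models = build_gene_models(
            Path(config.annotation).read_text(),
            flank_bp=config.flank_bp,
            chrom_sizes=chrom_sizes,
        )
        report_ck = dio.read_cytosine_report(config.report_ck)
        report_atr = dio.read_cytosine_report(config.report_atr)

    with stage("call"):
        if config.control_sites:
            ctrl = pd.read_csv(config.control_sites, sep="\t")
            key = ["chrom", "pos", "strand"]
            ctrl["pos"] = ctrl["pos"].astype(int) - 1
            merged = report_ck.merge(ctrl[key], on=key)
            eps = estimate_nonconversion(
                merged["count_methylated"], merged["count_unmethylated"]
            )
        elif config.nonconversion is not None:
            eps = config.nonconversion
        else:
            eps = 0.004
            logger.warning(
                "no non-conversion rate or control sites supplied; "
                "assuming epsilon = %.3g",
                eps,
            )
        calls_ck = call_methylome(report_ck, eps, config.calling_fdr, config.min_coverage)
        calls_atr = call_methylome(report_atr, eps, config.calling_fdr, config.min_coverage)
        _write(calls_ck, out / "calls_ck.tsv", ["chrom", "pos", "strand"])
        _write(calls_atr, out / "calls_atr.tsv", ["chrom", "pos", "strand"])

    with stage("landscape"):
        comp = pd.DataFrame(
            {
                "condition": ["ck", "atr"],
                **{
                    ctx: [
                        context_composition(calls_ck).get(ctx),
                        context_composition(calls_atr).get(ctx),
                    ]
                    for ctx in ("CG", "CHG", "CHH")
                },
            }
        )
        _write(comp, out / "context_composition.tsv")
        for label, calls in (("ck", calls_ck), ("atr", calls_atr)):
            win = sliding_window_levels(calls, config.window, config.window_step)
            _write(win, out / f"windows_{label}.tsv", ["chrom", "start", "context"])
            prof = chromosome_profile(calls, config.chromosome_bin, config.smooth_bins)
            _write(prof, out / f"chromosome_profile_{label}.tsv", ["chrom", "start", "context"])
            meta = feature_metaprofile(calls, gene_models, config.metaprofile_bins)
            _write(meta, out / f"metaprofile_{label}.tsv", ["region", "bin", "context"])

    with stage("diff"):
        feats_ck = feature_methylation(
            calls_ck, gene_models, library_mode=config.library_mode
        )
        feats_atr = feature_methylation(
            calls_atr, gene_models, library_mode=config.library_mode
        )
        diff = call_differential_features(
            feats_atr, feats_ck, fdr=config.diff_fdr, fold=config.diff_fold
        )
        _write(diff, out / "diff_features.tsv", ["gene", "region", "context"])
        dmg = summarize_dmgs(diff)
        _write(dmg, out / "dmg_summary.tsv", ["gene"])
        overlap = region_direction_overlap(diff)
        _write(overlap, out / "dmg_region_overlap.tsv", ["gene"])
        win_ck = window_methylation(
            calls_ck, config.window, config.window_step, library_mode=config.library_mode
        )
        win_atr = window_methylation(
            calls_atr, config.window, config.window_step, library_mode=config.library_mode
        )
        dmrs = call_dmrs(
            win_atr, win_ck, fdr=config.diff_fdr, fold=config.diff_fold, merge_gap=config.merge_gap
        )
        bed = dmrs.copy()
        bed["name"] = bed["context"] + "_" + bed["direction"]
        bed["strand"] = "."
        if len(bed):
            dio.write_bed6(bed, out / "dmrs.bed")
        else:
            (out / "dmrs.bed").write_text("")
        _write(dmrs, out / "dmrs.tsv", ["chrom", "start", "context"])

    with stage("integrate"):
        if config.expression:
            expr = dio.read_expression_table(config.expression)
            de = call_de(expr, fdr=config.de_fdr, min_log2fc=config.de_min_log2fc)
            _write(de, out / "de.tsv", ["gene"])
            joint = joint_filter(
                diff, de, p_meth=config.joint_p_meth, fold_meth=config.joint_fold_meth
            )
            _write(joint, out / "joint.tsv", ["gene", "region", "context"])
            counts = joint_region_counts(joint)
            _write(counts, out / "joint_region_counts.tsv")
            classes = None
            if config.gene_classes:
                cls_df = pd.read_csv(config.gene_classes, sep="\t")
                classes = dict(zip(cls_df.iloc[:, 0], cls_df.iloc[:, 1]))
            assoc = association_summary(diff, de, classes)
            _write(assoc, out / "association.tsv", ["region", "gene_class"])
        else:
            de = pd.DataFrame()
            joint = pd.DataFrame()
            assoc = pd.DataFrame()

    with stage("mirna"):
        if config.mirna_loci:
            loci = dio.read_bed_intervals(config.mirna_loci)
            ml_atr = locus_methylation(calls_atr, loci)
            ml_ck = locus_methylation(calls_ck, loci)
            mirna = compare_locus_methylation(ml_atr, ml_ck)
            mirna["passes_two_fold"] = (
                mirna["log2_ratio"].abs() >= config.mirna_min_abs_log2
            ) & np.isfinite(mirna["log2_ratio"])
            _write(mirna, out / "mirna_loci.tsv", ["name"])
        else:
            mirna = None

    with stage("summary"):
        sig = diff[diff["significant"]]
        summary = {
            "n_sites_tested_ck": int(len(calls_ck)),
            "n_sites_tested_atr": int(len(calls_atr)),
            "n_mc_ck": int(calls_ck["is_methylated"].sum()),
            "n_mc_atr": int(calls_atr["is_methylated"].sum()),
            "n_dmrs": int(len(dmrs)),
            "n_dmgs": int(dmg["gene"].nunique()) if len(dmg) else 0,
            "n_dmgs_hyper": int((dmg["classification"] == "hyper").sum()) if len(dmg) else 0,
            "n_dmgs_hypo": int((dmg["classification"] == "hypo").sum()) if len(dmg) else 0,
            "n_dmgs_mixed": int((dmg["classification"] == "mixed").sum()) if len(dmg) else 0,
            "n_de_genes": int(de["significant"].sum()) if len(de) else 0,
            "n_joint_genes": int(joint["gene"].nunique()) if len(joint) else 0,
            "n_mirna_loci_two_fold": (
                int(mirna["passes_two_fold"].sum()) if mirna is not None else 0
            ),
        }
        # timings go to the log only, keeping outputs byte-stable across reruns
        logger.info("stage timings (s): %s", timings)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        calls_ck=calls_ck,
        calls_atr=calls_atr,
        diff_features=diff,
        dmrs=dmrs,
        dmg_summary=dmg,
        de=de,
        joint=joint,
        association=assoc,
        mirna=mirna,
        summary=summary,
    )
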