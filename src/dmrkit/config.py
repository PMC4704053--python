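"""Run configuration: paths, thresholds and the seed, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    # input paths
    genome: str = ""
    annotation: str = ""
    report_ck: str = ""
    report_atr: str = ""
    expression: str = ""
    mirna_loci: str = ""
    gene_classes: str = ""  # optional two-column TSV: gene, class
    control_sites: str = ""  # optional known-unmethylated sites for epsilon
    out_dir: str = "dmrkit_out"
    # methylcytosine calling
    calling_fdr: float = 0.01
    min_coverage: int = 4
    nonconversion: float | None = None  # estimated from data when None
    # landscape
    window: int = 200
    window_step: int | None = None
    chromosome_bin: int = 10_000
    smooth_bins: int = 5
    metaprofile_bins: int = 20
    # gene regions
    flank_bp: int = 2000
    # differential methylation
    diff_fdr: float = 0.05
    diff_fold: float = 2.0
    merge_gap: int = 0
    library_mode: str = "methylation_reads"
    # differential expression
    de_fdr: float = 0.001
    de_min_log2fc: float = 1.0
    # joint filter
    joint_p_meth: float = 0.05
    joint_fold_meth: float = 2.0
    # miRNA loci
    mirna_min_abs_log2: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "calling_fdr",
            "min_coverage",
            "window",
            "chromosome_bin",
            "metaprofile_bins",
            "flank_bp",
            "diff_fdr",
            "diff_fold",
            "de_fdr",
            "de_min_log2fc",
            "joint_p_meth",
            "joint_fold_meth",
            "mirna_min_abs_log2",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("genome", "annotation", "report_ck", "report_atr"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"required input path {name!r} not set")
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        for name in ("expression", "mirna_loci", "gene_classes", "control_sites"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
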