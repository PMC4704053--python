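"""Synthetic bisulfite-sequencing data with known ground truth.

Generates genomes, gene annotations, true methylomes, per-site
bisulfite pileup counts for two conditions (control "CK" and treatment
"ATR"), and expression counts coupled to the treatment's methylation
effects -- everything the downstream pipeline consumes, alongside truth
tables for validation.

The default methylome preset reproduces the qualitative structure of a
plant (rice) methylome under a stress treatment:

* context hierarchy CG > CHG > CHH in both the per-site level
  distribution (Beta means 0.6 / 0.35 / 0.1) and the fraction of sites
  truly methylated (0.5 / 0.4 / 0.1);
* bisulfite non-conversion rate epsilon = 0.004 (conversion ~99.6%);
* mean sequencing depth 20x per strand (Poisson by default; a
  fixed-depth switch exists for deterministic tests);
* treatment effects as per-gene-region level shifts (default magnitude
  0.35 on the level scale) -- a stand-in for the unknown true
  effect-size distribution of stress-induced methylation changes;
* expression coupling: genes hypermethylated upstream are
  down-regulated (log2FC -1), genes hypomethylated in the genebody are
  up-regulated (+1), neutral otherwise, plus Gaussian noise.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams, so every artefact is
bit-reproducible and independent components can be regenerated in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dmrkit.genome import CONTEXTS, GeneModel, enumerate_cytosines, write_fasta
from dmrkit import io as dio

DEFAULT_BETA_MEAN = {"CG": 0.6, "CHG": 0.35, "CHH": 0.1}
DEFAULT_METHYLATED_FRACTION = {"CG": 0.5, "CHG": 0.4, "CHH": 0.1}


@dataclass(frozen=True)
class TreatmentEffect:
    """A targeted methylation change in the treatment condition.

    ``direction`` is "hyper" or "hypo"; ``effect_size`` is the shift on
    the methylation-level scale applied to every site of ``context``
    within ``region`` of ``gene_id`` (clamped to [0, 1]).
    """

    gene_id: str
    region: str
    context: str
    direction: str
    effect_size: float


@dataclass
class MethylomeModel:
    """Parameters of the simulated methylome and sequencing noise."""

    beta_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_MEAN))
    beta_concentration: float = 10.0
    methylated_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHYLATED_FRACTION)
    )
    nonconversion: float = 0.004
    seq_error_to_c: float = 0.0
    mean_depth: float = 20.0
    fixed_depth: bool = False

    def validate(self) -> None:
        for name, d in (("beta_mean", self.beta_mean), ("methylated_fraction", self.methylated_fraction)):
            for ctx, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{name}[{ctx}] = {v} outside [0, 1]")
        if not 0 <= self.nonconversion < 1:
            raise ValueError("nonconversion must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


class UnknownEffectTarget(KeyError):
    """A treatment effect names a gene absent from the annotation."""


def _rng(seed_seq: np.random.SeedSequence, *path: str) -> np.random.Generator:
    """Named substream: same master seed + same path => same stream.

    The spawn key is derived from the path strings, so substreams do not
    depend on the order in which components request them.
    """
    key = tuple(int.from_bytes(p.encode(), "little") % (2**31) for p in path)
    return np.random.default_rng(np.random.SeedSequence(seed_seq.entropy, spawn_key=key))


def simulate_genome(
    n_chrom: int, chrom_len: int, gc_fraction: float, seed: int
) -> dict[str, str]:
    """I.i.d. random genome at a target GC content.

    Deterministic for a fixed seed; ``gc_fraction`` must lie strictly
    between 0 and 1.
    """
    if chrom_len < 1:
        raise ValueError("chrom_len must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    ss = np.random.SeedSequence(seed)
    genome = {}
    for i in range(n_chrom):
        rng = _rng(ss, f"chrom{i}")
        p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=chrom_len, p=p)
        genome[f"chr{i + 1}"] = bases.tobytes().decode()
    return genome


def place_genes(
    genome: Mapping[str, str],
    genes_per_chrom: int,
    gene_len: int = 600,
    flank: int = 300,
    gap: int = 200,
    margin: int = 200,
) -> tuple[str, list[GeneModel]]:
    """Deterministically tile non-overlapping genes along each chromosome.

    Genes alternate strand.  Returns the GFF3 text and the matching
    :class:`GeneModel` list (flank length = ``flank``).  Raises if the
    chromosomes are too short for the requested layout.
    """
    slot = flank + gene_len + flank + gap
    lines = ["##gff-version 3"]
    models = []
    gi = 0
    for chrom in sorted(genome):
        clen = len(genome[chrom])
        need = margin + genes_per_chrom * slot + margin
        if clen < need:
            raise ValueError(
                f"chromosome {chrom} ({clen} bp) too short for "
                f"{genes_per_chrom} gene slots ({need} bp)"
            )
        for j in range(genes_per_chrom):
            start = margin + j * slot + flank  # 0-based genebody start
            end = start + gene_len
            strand = "+" if (gi % 2 == 0) else "-"
            gid = f"gene{gi + 1:04d}"
            lines.append(
                "\t".join(
                    [chrom, "dmrkit_sim", "gene", str(start + 1), str(end), ".", strand, ".", f"ID={gid}"]
                )
            )
            left = (start - flank, start)
            right = (end, end + flank)
            upstream, downstream = (left, right) if strand == "+" else (right, left)
            models.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    genebody=(start, end),
                    upstream=upstream,
                    downstream=downstream,
                )
            )
            gi += 1
    return "\n".join(lines) + "\n", models


def place_mirna_loci(
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    n_loci: int,
    locus_len: int = 150,
) -> pd.DataFrame:
    """Place miRNA precursor intervals in the gaps between gene slots."""
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gm in gene_models:
        lo = min(gm.upstream[0], gm.genebody[0], gm.downstream[0])
        hi = max(gm.upstream[1], gm.genebody[1], gm.downstream[1])
        occupied.setdefault(gm.chrom, []).append((lo, hi))
    rows = []
    li = 0
    for chrom in sorted(genome):
        if li >= n_loci:
            break
        ivs = sorted(occupied.get(chrom, []))
        clen = len(genome[chrom])
        gaps = []
        prev = 0
        for s, e in ivs:
            if s - prev >= locus_len:
                gaps.append((prev, s))
            prev = max(prev, e)
        if clen - prev >= locus_len:
            gaps.append((prev, clen))
        for gs, ge in gaps:
            if li >= n_loci:
                break
            rows.append(
                {"chrom": chrom, "start": gs, "end": gs + locus_len, "name": f"MIRSYN{li + 1:03d}"}
            )
            li += 1
    if li < n_loci:
        import logging

        logging.getLogger(__name__).warning(
            "could only place %d of %d miRNA loci in intergenic gaps", li, n_loci
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def simulate_methylome(
    sites: pd.DataFrame,
    model: MethylomeModel,
    seed: int,
    gene_models: Sequence[GeneModel] = (),
    effects: Sequence[TreatmentEffect] = (),
) -> pd.DataFrame:
    """Assign true methylation levels per site for control and treatment.

    Each site is truly methylated with its context's
    ``methylated_fraction``; methylated sites draw their level from a
    Beta with the context's mean and the shared concentration,
    unmethylated sites have level 0.  The treatment methylome equals the
    control except at effect targets, where the level is shifted by
    ``effect_size`` (sign per direction) and clamped to [0, 1].

    Returns the site table with added ``level_ck`` and ``level_atr``.
    """
    model.validate()
    ss = np.random.SeedSequence(seed)
    out = sites.copy().reset_index(drop=True)
    n = len(out)
    level = np.zeros(n)
    ctx_arr = out["context"].to_numpy()
    for ctx in CONTEXTS:
        rng = _rng(ss, f"methylome_{ctx}")
        mask = ctx_arr == ctx
        k = int(mask.sum())
        if k == 0:
            continue
        frac = model.methylated_fraction.get(ctx, 0.0)
        mean = model.beta_mean.get(ctx, 0.0)
        conc = model.beta_concentration
        is_meth = rng.random(k) < frac
        lv = np.zeros(k)
        if is_meth.any() and mean > 0:
            a, b = mean * conc, (1 - mean) * conc
            lv[is_meth] = rng.beta(a, b, size=int(is_meth.sum()))
        level[mask] = lv
    out["level_ck"] = level
    atr = level.copy()
    if effects:
        by_id = {gm.gene_id: gm for gm in gene_models}
        pos_arr = out["pos"].to_numpy()
        chrom_arr = out["chrom"].to_numpy()
        for eff in effects:
            gm = by_id.get(eff.gene_id)
            if gm is None:
                raise UnknownEffectTarget(eff.gene_id)
            s, e = gm.region(eff.region)
            mask = (chrom_arr == gm.chrom) & (pos_arr >= s) & (pos_arr < e) & (ctx_arr == eff.context)
            shift = eff.effect_size if eff.direction == "hyper" else -eff.effect_size
            atr[mask] = np.clip(atr[mask] + shift, 0.0, 1.0)
    out["level_atr"] = atr
    return out


def simulate_bisulfite_counts(
    truth: pd.DataFrame,
    model: MethylomeModel,
    seed: int,
    condition: str = "ck",
) -> pd.DataFrame:
    """Draw per-site pileup counts from the true levels of one condition.

    Depth per site (one strand each row) is Poisson with the model's
    mean (or exactly the mean when ``fixed_depth``).  The probability a
    read reports C is ``m*(1 - err) + (1 - m)*epsilon`` for true level
    ``m``: methylated templates fail only by sequencing error, while
    unmethylated templates escape conversion at rate epsilon.  Zero-
    depth sites are retained with 0/0 counts (filtered downstream).
    """
    model.validate()
    level_col = f"level_{condition}"
    if level_col not in truth.columns:
        raise KeyError(level_col)
    ss = np.random.SeedSequence(seed)
    rng = _rng(ss, f"counts_{condition}")
    n = len(truth)
    if model.fixed_depth:
        depth = np.full(n, int(round(model.mean_depth)))
    else:
        depth = rng.poisson(model.mean_depth, size=n)
    m = truth[level_col].to_numpy()
    p_c = m * (1 - model.seq_error_to_c) + (1 - m) * model.nonconversion
    k = rng.binomial(depth, p_c)
    out = truth[["chrom", "pos", "strand"]].copy()
    out["count_methylated"] = k
    out["count_unmethylated"] = depth - k
    out["context"] = truth["context"].to_numpy()
    return out


def default_expression_coupling(effect: TreatmentEffect) -> float:
    """Expression log2FC implied by a methylation effect.

    Upstream hypermethylation represses (-1); genebody hypomethylation
    activates (+1); all other region/direction combinations are neutral.
    """
    if effect.region == "upstream" and effect.direction == "hyper":
        return -1.0
    if effect.region == "genebody" and effect.direction == "hypo":
        return 1.0
    return 0.0


def simulate_expression(
    gene_ids: Sequence[str],
    true_log2fc: Mapping[str, float],
    seed: int,
    lib_ck: int = 2_000_000,
    lib_atr: int = 2_000_000,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Poisson expression counts for two conditions with known log2FCs.

    Baseline relative expression per gene is log-normal; treatment means
    are scaled by ``2**(log2FC + noise)``.  Returns ``gene, count_ck,
    count_atr, true_log2fc`` (the noisy realised value).
    """
    ss = np.random.SeedSequence(seed)
    rng = _rng(ss, "expression")
    n = len(gene_ids)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    lfc = np.array([true_log2fc.get(g, 0.0) for g in gene_ids])
    if noise_sd > 0:
        lfc = lfc + rng.normal(0.0, noise_sd, size=n)
    rel_ck = base / base.sum()
    w_atr = base * np.exp2(lfc)
    rel_atr = w_atr / w_atr.sum()
    count_ck = rng.poisson(lib_ck * rel_ck)
    count_atr = rng.poisson(lib_atr * rel_atr)
    return pd.DataFrame(
        {"gene": list(gene_ids), "count_ck": count_ck, "count_atr": count_atr, "true_log2fc": lfc}
    )


@dataclass
class SyntheticDataset:
    """In-memory bundle of one simulated experiment plus its truth."""

    genome: dict[str, str]
    gff_text: str
    gene_models: list[GeneModel]
    sites: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_features: pd.DataFrame
    report_ck: pd.DataFrame
    report_atr: pd.DataFrame
    expression: pd.DataFrame
    mirna_loci: pd.DataFrame
    effects: list[TreatmentEffect]
    model: MethylomeModel


def default_effects(
    gene_models: Sequence[GeneModel],
    fraction_affected: float = 0.2,
    effect_size: float = 0.35,
    seed: int = 0,
) -> list[TreatmentEffect]:
    """Default treatment-effect set: of the affected genes, half gain
    upstream CG methylation and half lose genebody CG methylation."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    ids = [gm.gene_id for gm in gene_models]
    n_aff = int(round(fraction_affected * len(ids)))
    chosen = rng.choice(len(ids), size=n_aff, replace=False)
    effects = []
    for i, idx in enumerate(sorted(chosen)):
        if i % 2 == 0:
            effects.append(TreatmentEffect(ids[idx], "upstream", "CG", "hyper", effect_size))
        else:
            effects.append(TreatmentEffect(ids[idx], "genebody", "CG", "hypo", effect_size))
    return effects


def simulate_dataset(
    seed: int,
    n_chrom: int = 2,
    genes_per_chrom: int = 10,
    gene_len: int = 600,
    flank: int = 2000,
    gc_fraction: float = 0.43,
    model: MethylomeModel | None = None,
    effects: Sequence[TreatmentEffect] | None = None,
    fraction_affected: float = 0.2,
    effect_size: float = 0.35,
    n_mirna_loci: int = 8,
    lib_ck: int = 2_000_000,
    lib_atr: int = 2_000_000,
    expression_noise_sd: float = 0.25,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a complete two-condition experiment with truth tables.

    When ``out_dir`` is given, writes genome FASTA, annotation GFF3,
    cytosine reports for both conditions, expression table, miRNA locus
    BED and truth TSVs there.
    """
    model = model or MethylomeModel()
    gap, margin = 200, 200
    slot = flank + gene_len + flank + gap
    chrom_len = margin + genes_per_chrom * slot + margin
    genome = simulate_genome(n_chrom, chrom_len, gc_fraction, seed)
    gff_text, gene_models = place_genes(genome, genes_per_chrom, gene_len, flank, gap, margin)
    sites = enumerate_cytosines(genome)
    if effects is None:
        effects = default_effects(gene_models, fraction_affected, effect_size, seed)
    truth_sites = simulate_methylome(sites, model, seed, gene_models, effects)
    report_ck = simulate_bisulfite_counts(truth_sites, model, seed, "ck")
    report_atr = simulate_bisulfite_counts(truth_sites, model, seed, "atr")
    effect_map = {(e.gene_id, e.region, e.context): e for e in effects}
    feat_rows = []
    for gm in gene_models:
        for region in ("upstream", "genebody", "downstream"):
            for ctx in CONTEXTS:
                e = effect_map.get((gm.gene_id, region, ctx))
                feat_rows.append(
                    {
                        "gene": gm.gene_id,
                        "region": region,
                        "context": ctx,
                        "is_differential": e is not None,
                        "direction": e.direction if e else "none",
                        "effect_size": e.effect_size if e else 0.0,
                    }
                )
    truth_features = pd.DataFrame(feat_rows)
    lfc_map = {e.gene_id: default_expression_coupling(e) for e in effects}
    expression = simulate_expression(
        [gm.gene_id for gm in gene_models], lfc_map, seed, lib_ck, lib_atr, expression_noise_sd
    )
    mirna_loci = place_mirna_loci(genome, gene_models, n_mirna_loci)
    ds = SyntheticDataset(
        genome=genome,
        gff_text=gff_text,
        gene_models=gene_models,
        sites=sites,
        truth_sites=truth_sites,
        truth_features=truth_features,
        report_ck=report_ck,
        report_atr=report_atr,
        expression=expression,
        mirna_loci=mirna_loci,
        effects=list(effects),
        model=model,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        (out / "annotation.gff3").write_text(gff_text)
        dio.write_cytosine_report(report_ck, out / "report_ck.tsv")
        dio.write_cytosine_report(report_atr, out / "report_atr.tsv")
        expression[["gene", "count_ck", "count_atr"]].to_csv(
            out / "expression.tsv", sep="\t", index=False
        )
        mirna_loci[["chrom", "start", "end", "name"]].to_csv(
            out / "mirna_loci.bed", sep="\t", index=False, header=False
        )
        t = truth_sites.copy()
        t["pos"] = t["pos"] + 1
        t.to_csv(out / "truth_sites.tsv", sep="\t", index=False, float_format="%.6g")
        truth_features.to_csv(out / "truth_features.tsv", sep="\t", index=False, float_format="%.6g")
        expression.to_csv(out / "truth_expression.tsv", sep="\t", index=False, float_format="%.6g")
    return ds
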