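"""Genome and annotation handling: cytosine context enumeration and gene region models.

Plant methylomes are analysed in three sequence contexts -- CG, CHG and
CHH (H = A, C or T) -- which are maintained by distinct methyltransferase
pathways.  The context of a cytosine is determined by the two bases
immediately 3' of it *on its own strand*; for a reverse-strand cytosine
(a G on the forward reference) those are the reverse-complemented bases
immediately 5' of the G.

All internal coordinates are 0-based half-open.  GFF3 input (1-based,
closed) is converted on read; TSV output positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
REGIONS = ("upstream", "genebody", "downstream")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class CytosineSite(NamedTuple):
    """One genomic cytosine with strand and sequence context.

    ``pos`` is the 0-based position of the cytosine base on the forward
    coordinate system (for a minus-strand site this is the position of
    the G on the forward strand).
    """

    chrom: str
    pos: int
    strand: str
    context: str


@dataclass
class GeneModel:
    """A gene with its flanking regions and optional sub-features.

    Intervals are 0-based half-open ``(start, end)`` tuples on the
    forward coordinate system.  ``upstream`` is 5' of the transcription
    start *on the gene's own strand*, so for a minus-strand gene it lies
    at higher forward coordinates than the genebody.
    """

    gene_id: str
    chrom: str
    strand: str
    genebody: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    subfeatures: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def region(self, name: str) -> tuple[int, int]:
        if name == "genebody":
            return self.genebody
        if name == "upstream":
            return self.upstream
        if name == "downstream":
            return self.downstream
        raise KeyError(name)

    def region_length(self, name: str) -> int:
        s, e = self.region(name)
        return max(0, e - s)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N}."""
    return seq.upper().encode().translate(_COMPLEMENT)[::-1].decode()


def _classify(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Context codes from the two downstream bases (uint8 ASCII arrays).

    Returns an int array: 0=CG, 1=CHG, 2=CHH, -1=invalid (N or non-H base
    where H is required).
    """
    G = ord("G")
    N = ord("N")
    out = np.full(b1.shape, -1, dtype=np.int8)
    valid1 = b1 != N
    valid2 = b2 != N
    is_cg = valid1 & (b1 == G)
    # H = A, C or T: any valid base that is not G
    is_h1 = valid1 & (b1 != G)
    is_chg = is_h1 & valid2 & (b2 == G)
    is_chh = is_h1 & valid2 & (b2 != G)
    out[is_cg & valid2] = 0
    out[is_chg] = 1
    out[is_chh] = 2
    return out


def enumerate_cytosines(genome: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its sequence context.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence (alphabet {A,C,G,T,N},
        case-insensitive).

    Returns
    -------
    DataFrame with columns ``chrom, pos, strand, context`` sorted by
    (chrom, pos, strand).  Sites whose two-base context window contains
    an N or runs off the chromosome end are skipped.
    """
    frames = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise AlphabetError(
                f"chromosome {chrom!r} position {i}: invalid base {chr(arr[i])!r}"
            )
        n = len(arr)
        if n == 0:
            continue
        C, G = ord("C"), ord("G")
        # forward strand: C with two bases 3' of it on the reference
        fwd = np.flatnonzero(arr[: max(0, n - 2)] == C)
        ctx_f = _classify(arr[fwd + 1], arr[fwd + 2]) if fwd.size else np.empty(0, np.int8)
        keep = ctx_f >= 0
        fwd, ctx_f = fwd[keep], ctx_f[keep]
        # reverse strand: G on the reference; downstream on the minus
        # strand = complement of the two bases 5' of the G
        rev = np.flatnonzero(arr[2:] == G) + 2
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b
        ctx_r = (
            _classify(comp[arr[rev - 1]], comp[arr[rev - 2]])
            if rev.size
            else np.empty(0, np.int8)
        )
        keep = ctx_r >= 0
        rev, ctx_r = rev[keep], ctx_r[keep]

        pos = np.concatenate([fwd, rev])
        strand = np.concatenate(
            [np.zeros(fwd.size, dtype=np.int8), np.ones(rev.size, dtype=np.int8)]
        )
        ctx = np.concatenate([ctx_f, ctx_r])
        order = np.lexsort((strand, pos))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[order],
                    "strand": np.array(["+", "-"])[strand[order]],
                    "context": np.array(CONTEXTS)[ctx[order]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_gene_models(
    annotation,
    flank_bp: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Build strand-aware gene region models from GFF3 annotation.

    Parameters
    ----------
    annotation
        Path to a GFF3 file, or a string of GFF3 text.
    flank_bp
        Length of the upstream and downstream flanks; truncated at
        chromosome edges (and at 0).
    chrom_sizes
        Optional chromosome lengths used to truncate downstream flanks.

    Notes
    -----
    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Sub-features (five_prime_UTR, CDS, three_prime_UTR) are collected per
    gene when present; introns are derived as gaps between exons.  Genes
    without usable coordinates are skipped with a warning.
    """
    import gffutils

    data = str(annotation)
    from_string = "\t" in data or "\n" in data
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        try:
            start = gene.start - 1  # to 0-based
            end = gene.end
            strand = gene.strand if gene.strand in "+-" else "+"
        except (TypeError, AttributeError):
            logger.warning("gene %s has no usable coordinates; skipped", gene.id)
            continue
        if start is None or end is None or end <= start:
            logger.warning("gene %s has no usable coordinates; skipped", gene.id)
            continue
        size = chrom_sizes.get(gene.seqid) if chrom_sizes else None
        left = (max(0, start - flank_bp), start)
        right_end = end + flank_bp if size is None else min(size, end + flank_bp)
        right = (end, max(end, right_end))
        if strand == "+":
            upstream, downstream = left, right
        else:
            upstream, downstream = right, left
        sub: dict[str, list[tuple[int, int]]] = {}
        exons = []
        for child in db.children(gene, order_by="start"):
            ftype = child.featuretype
            iv = (child.start - 1, child.end)
            if ftype == "exon":
                exons.append(iv)
            elif ftype in ("five_prime_UTR", "CDS", "three_prime_UTR"):
                key = {"five_prime_UTR": "5UTR", "CDS": "CDS", "three_prime_UTR": "3UTR"}[ftype]
                sub.setdefault(key, []).append(iv)
        if len(exons) > 1:
            exons.sort()
            introns = [
                (exons[i][1], exons[i + 1][0])
                for i in range(len(exons) - 1)
                if exons[i + 1][0] > exons[i][1]
            ]
            if introns:
                sub["intron"] = introns
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                genebody=(start, end),
                upstream=upstream,
                downstream=downstream,
                subfeatures=sub,
            )
        )
    return models


def sites_to_tsv(sites: pd.DataFrame, path) -> None:
    """Write a site table as TSV with 1-based positions."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
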