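# Methods

## Scope and data model

dmrkit starts from per-site bisulfite cytosine counts (the "cytosine
report": chrom, 1-based position, strand, methylated count,
unmethylated count, context), not from reads; alignment and read-level
processing are upstream of the package. Internally all coordinates are
0-based half-open; GFF3 (1-based closed) and report files are converted
at the I/O boundary. A cytosine's context (CG / CHG / CHH, H ∈ {A,C,T})
is determined by the two bases 3′ of it on its own strand; sites whose
two-base window contains an N or runs off the chromosome end are
excluded from all statistics rather than given a fallback context, to
avoid misclassification.

## Methylcytosine calling

Per site, the one-sided exact binomial p-value P[X ≥ k | n, ε] tests
the null that all C readouts arise from incomplete bisulfite conversion
at rate ε. Design choices, all exposed in configuration:

* **ε floor 10⁻⁴** — a control set with zero unconverted reads would
  otherwise produce degenerate p-values.
* **Coverage floor 4 reads** (default) — sites below it are excluded
  from testing entirely, stabilising ML estimates; they carry no
  p-value rather than p = 1.
* **One BH family per condition, genome-wide across contexts** at FDR
  1%. Context-stratified adjustment is a defensible alternative; the
  single family matches a single genome-wide FDR statement and is the
  default.
* **Strand handling** — sites are tested per strand as reported;
  `pool_cg_strands` merges the two strands of a symmetric CG
  dinucleotide for level reporting (pooled ML is by construction the
  count-weighted combination of per-strand MLs).

ML = mC/(mC + non-mC) is reported for every tested site regardless of
the call.

## Landscapes

All summaries pool read counts (Σ mC / Σ total), never averages of
per-site MLs: pooling matches the ML definition and downweights
low-coverage sites. Windows (default 200 bp) tile from coordinate 0;
`step < width` gives overlapping sliding windows, the default is
non-overlapping. Chromosome profiles use 10 kb bins with an optional
centred moving average (default 5 bins, NaN bins skipped). Gene
metaprofiles rescale each region (upstream / genebody / downstream,
plus 5′UTR/CDS/intron/3′UTR where annotated) to a fixed number of bins,
oriented 5′→3′ on the gene's strand, pooling counts across genes per
bin. Windows or bins with no covered site of a context are absent/NaN
for that context.

## Differential methylation

Counts of methylation-supporting reads are pooled per gene × region ×
context and normalised as RKTM = count / ((len/10³)·(library/10⁶)).
The library total is the condition's methylation-supporting read count
(switchable to total coverage via `library_mode="all_reads"`). The test
is a two-sided Fisher's exact on the pooled 2×2 (mC, non-mC) table —
two-sided because hyper- and hypomethylation are both of interest.
Significance requires BH FDR < 0.05 (one family over all gene × region
× context tests of the run) **and** max(RKTM_t/RKTM_c, RKTM_c/RKTM_t) >
2. When one side's count is zero, the fold change uses a pseudocount of
0.5 reads converted through that side's RKTM unit; the Fisher table is
never pseudocounted, so the exact test is undistorted. Direction is
hyper iff treatment ML > control ML (ties, which cannot be significant,
fall to hypo). A zero Fisher margin yields p = 1 by convention.

DMRs: the identical test over aligned window tilings; significant
windows of equal chromosome, context and direction merge when their gap
is ≤ `merge_gap` (default 0, i.e. adjacent windows only). The DMG
summary keeps per-region directions un-collapsed: a gene hyper in one
region and hypo in another is retained with both labels and classified
"mixed".

## Expression integration

The no-replicate differential expression test is the Audic–Claverie
exact test: conditioned on count x in library 1, the null distribution
of count y in library 2 is negative binomial with r = x+1 and success
probability N₁/(N₁+N₂). The two-sided p is 2·min(tails), capped at 1.
Because this construction is not symmetric in the two libraries, the
implementation averages the p-values of both orientations, making the
test exactly invariant under swapping (count, library) pairs. This
choice of test for unreplicated count libraries is an interpretation —
the interface (`call_de`) is a thin wrapper and alternatives can be
substituted. log₂ fold changes use library-size-normalised counts with
a pseudocount of 1; DE requires BH FDR ≤ 0.001 and |log₂FC| ≥ 1.

The joint methylation–expression filter deliberately uses the *raw*
methylation p < 0.05 with fold ratio ≥ 2 — a looser screen than the
FDR-based DMG caller — together with the DE flag; both the DMG counts
and the joint counts appear in the pipeline summary. The association
summary collapses contexts per gene × region (keeping the context with
the smallest p), computes the methylation log₂ RKTM ratio, and reports
Spearman rank correlations and quadrant counts against expression
log₂FC per region and gene class.

## miRNA loci

Pooled ML over all covered cytosines of a precursor interval, all
contexts together (a single ML per locus); log₂(ML_t/ML_c) is undefined
(NaN, excluded from the two-fold filter) when either level is zero or
the locus has no covered cytosine. Ratios are kept at full precision
and rounded to 2 decimals only at reporting.

The packaged reference table (`data/mirna_loci_ml.tsv`) of published
per-locus methylation levels at rice miRNA precursor loci under
atrazine exposure carries a computed `consistent` flag: for 5 of the 15
rows the printed "log₂" column is actually the raw ML ratio (e.g.
0.45/0.21 printed as 2.14 where log₂ = 1.10). These rows are flagged,
never silently corrected. On the *recomputed* log₂ values all 15 loci
still pass the two-fold filter.

## Synthetic data

The generator emulates a pooled two-condition plant WGBS experiment:

* **Methylome preset** — Beta-distributed levels for truly methylated
  sites with means CG 0.6 / CHG 0.35 / CHH 0.1 (shared concentration
  10) and methylated fractions 0.5 / 0.4 / 0.1, reproducing the plant
  context hierarchy; with this preset the context composition of called
  mCs comes out ≈ 55% CG / 33% CHG / 12% CHH.
* **Noise model** — per-strand depth Poisson(20) (fixed-depth switch
  for deterministic tests); a read reports C with probability
  m·(1−err) + (1−m)·ε, ε = 0.004, err = 0 by default.
* **Treatment effects** — per (gene, region, context) level shifts,
  clamped to [0,1]. The default magnitude 0.35 (and the +0.4 used in
  the recovery analyses) is a stand-in: no quantitative effect-size
  distribution for stress-induced methylation change is established,
  so these values should not be read as biologically calibrated.
* **Expression coupling** — upstream hyper ⇒ log₂FC −1, genebody hypo
  ⇒ +1, neutral otherwise, plus N(0, 0.25) noise; counts are Poisson
  with log-normal baselines at 2 M reads per library.
* **Geometry** — genes tiled deterministically (600 bp bodies, 2 kb
  flanks matching the analysis default, alternating strands), miRNA
  loci placed in intergenic gaps, GC 0.43.

All randomness flows from one master seed through named SeedSequence
substreams, so artefacts are bit-reproducible and independent of the
order in which components draw.

What the simulations do **not** capture: non-uniform coverage and
mappability, methylation autocorrelation along the genome (levels are
independent across sites given context), biological replicates and
overdispersion beyond the Beta site-level variation, sequence
composition structure (i.i.d. bases), and partial/context-specific
conversion biases. Passing tests therefore demonstrate statistical
correctness of the machinery under its stated model, not robustness to
every artefact of real libraries.

## Problem sizes used in validation

Simulation-based checks run at desk scale: 10⁵ sites for the
null-calling false-call rate; 1000 genes (10 chromosomes × 100) for
differential null calibration and for effect recovery (100 affected
genes, +0.4 upstream-CG shift — with 2 kb flanks each upstream region
pools roughly 180 CG sites, giving recall ≈ 0.93–0.95 at zero realised
false discoveries); 500 genes for the association sign analysis; and a
~100 kb, 16–20-gene fixture for the end-to-end determinism check.

## Known limitations

* Fisher's exact test on pooled counts treats reads as independent;
  clustered methylation within a feature makes p-values optimistic.
  Beta-binomial or smoothing-based callers are out of scope.
* No replicate-aware DE model (dispersion estimation); the AC test is
  anti-conservative relative to biological replication.
* DMR boundaries are window-resolution; no base-pair refinement.
* The genebody definition is the annotated gene interval; whether
  introns should be excluded for some gene classes is left to the
  annotation supplied.
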