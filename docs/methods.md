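# Methods

## The sampling model of technical replication

A prepared Illumina-style RNA-seq library at 10 nmol/L in 400 µL contains
about 4 pmol of cDNA, i.e. ~2.4×10¹² molecules
(`estimate_library_molecules` multiplies moles in the tube by Avogadro's
number; with the constant 6.022×10²³ the exact value is 2.4088×10¹²). A
single lane sequences ~3×10⁷ of them — a sampling fraction of ~1.25×10⁻⁵
(0.0012–0.0013 %). `techvar` models lane-to-lane technical variability as
nothing but this sampling step:

1. **Expression profile.** Each of `n_genes` (default 20,000) genes draws
   an integer bin S_i uniformly from {0,…,17} (both endpoints included)
   and gets relative expression t_i = gamma(shape 2, scale 1) density at
   S_i, i.e. S_i·e^(−S_i). Most genes end up rare, a few abundant; a bin
   of 0 gives t_i = 0, so roughly 1/18 of genes are present in the
   annotation but absent from the library.
2. **Molecule pool.** g_i = round(t_i/Σt · N) molecules with
   N = 2.408×10¹² by default, round-half-to-even; the realized total
   Z = Σ g_i differs slightly from N because of rounding and is always the
   value used downstream.
3. **Replicates.** A technical replicate of n reads (default 3×10⁷;
   the test suite uses 3×10⁵–3×10⁶ to keep runtimes in seconds) is one
   multinomial(n, g/Z) draw. Drawing n uniform integer labels in 1..Z and
   tallying genes is distributionally identical; the multinomial form is
   used directly. Replicate seeds are `base_seed + replicate_index`, so an
   experiment is reproducible bit-for-bit from one integer.

Not modelled, deliberately: PCR/GC bias, mappability, insufficient-mixing
overdispersion (negative-binomial alternatives), sequencing error, splice
junctions and isoform structure. The model is the *null* — variation from
the sampling fraction alone — against which real discordance is judged.

## Genomic regions

Internal coordinates are 0-based half-open everywhere; the GFF3 reader
(1-based closed) is the only converter. Overlapping exons on one
chromosome are collapsed to their maximal union — merging requires at
least one shared base, so bookended exons stay separate — and strand is
ignored. Consensus contigs are maximal runs of positions with depth ≥
`min_depth` (default 3) in **every** lane of an experiment; they are the
annotation-free analysis unit.

## Quantitation

From a per-lane depth track and a region of length L:

- **detected**: any position with depth ≥ 1;
- **APN**: mean depth over all L positions, zeros included;
- **SD/CV**: the sample (n−1) standard deviation of per-base depth and
  CV = SD/APN. With uniform per-base depth definitions the (n) vs (n−1)
  choice is not prescribed anywhere authoritative; sample SD was chosen
  and is the only variant implemented. CV is reported as missing (NaN)
  when APN = 0 and such regions are excluded from CV profiles;
- **read count**: round(Σdepth / read_length) — exact when reads are fully
  contained in the region, as in the synthetic data;
- **RPKM**: (reads/L)·C/mappable_reads with C = 10⁹, the constant that
  makes the unit reads per kilobase per million mapped reads. C is
  configurable. `mappable_reads` is lane metadata (pileup header comment
  `#mappable_reads=` or caller argument) and is never inferred from depth.

Pileup dialects: classic 6-column samtools text pileup and a minimal
3-column TSV; both use 1-based file positions.

## Agreement statistics

RPKM is binned onto ordinal scales: three levels (0 undetected, 1
low–medium, 2 high with RPKM > 20) or nine levels (0 undetected — driven
by the detection flag, not by rounded RPKM — then half-open intervals
[0,10), [10,20), [20,40), [40,80), [80,160), [160,320), [320,1000),
[1000,∞)). A detected region with RPKM exactly 20 falls in category 3.

Simple agreement is the diagonal proportion; Cohen's kappa corrects it
for chance via the margin products. Weighted kappa uses linear
(Cicchetti–Allison) disagreement weights |i−j|/(k−1) by default — this is
the variant that reproduces the published 9-level statistic on the
packaged table (quadratic Fleiss–Cohen weights are available and give
0.92 there, which rules them out as the published choice). Degenerate
cases (chance agreement 1, expected weighted disagreement 0) return 1 for
a perfect table and raise otherwise.

Log-scale disagreement counts consider only region pairs with non-zero
RPKM in both replicates; the first threshold is inclusive ("1 log or
more"), later ones strict ("greater than 2 logs"). The log base defaults
to the natural log, consistent with the Bland–Altman analysis; it is
configurable because "a log" is genuinely ambiguous in this context.

## Concordance diagnostics

**Bland–Altman**: per pair, ((a+b)/2, a−b) on the raw or natural-log
scale; on the log scale pairs with a zero are excluded (no pseudocounts)
and counted separately. Bias = mean difference, limits of agreement =
bias ± 1.96·SD (the 1.96 multiplier is fixed). The bias-versus-average
smoother is a centered moving average (window 101 points) — a
deterministic substitute for loess that affects plots only, never the
statistics.

**CV profile**: (APN, CV) per region with APN > 0, a display flag for
APN ≤ 1000, and a cubic smoothing spline (scipy `UnivariateSpline`,
smoothing factor = number of distinct APN values, ties averaged) — again
deterministic and presentation-only.

**Detection model**: logit P(not present in all replicates) =
β₀ + β₁·abundance + β₂·length + β₃·abundance·length, fitted by
Newton/IRLS (convergence when the max coefficient change < 10⁻⁸, cap 50
iterations), restricted to regions observed in ≥ 1 replicate. Abundance
is mean RPKM across replicates and length is raw base pairs, both
unstandardized. Complete separation is detected (fitted probabilities
reproducing the responses) and raised as an error, as is a singular
design. Standard errors come from the inverse observed information.

## Synthetic coverage

The fixture generator tiles disjoint single-exon gene regions (lengths
uniform on [100, 500] bp by default, ≥ 10 bp gaps, read length 36) and
places each of a gene's reads at a start uniform over the legal window so
every read is fully contained in its gene. Consequences: the
depth → read-count round trip is exact (tested exactly), and
Σ depth = reads × read_length per lane. What this synthetic data does
*not* share with real data: junction/partially-overlapping reads,
multi-exon genes, non-uniform within-transcript coverage, mappability
holes. Tests passing on it therefore validate the accounting and the
statistics, not alignment-stage artefacts.

## Problem sizes and seeds

Default test/example scales: 20,000 genes with 3×10⁵–3×10⁶ reads per
replicate for pipeline-level properties (seconds per run), 100–5,000
genes for unit tests. All stochastic tests use fixed seeds; the
simulation defaults (20,000 genes, gamma(2,1) on 0–17, 2.408×10¹²
molecules, 3×10⁷ reads) are the study conditions and are configurable but
never silently changed.

One property of the model worth knowing: because the expression profile
is supported on 18 discrete abundance classes of roughly equal size,
detection kappa between two replicates improves only marginally with
depth — deeper sequencing detects many more genes in both lanes, but the
detection boundary moves to a rarer class of similar size, so the
discordant count stays near-constant. The improvement is strictly
positive at the fixed seeds used in the tests, but its magnitude is small
(~0.003 at a 10× depth increase).

## Known limitations

- The pipeline consumes pileup-level depth; it does not align reads, and
  multi-mapped reads, junctions and indels are out of scope.
- Isoform-level estimation is explicitly not attempted.
- Paired-end fragment-versus-read ambiguity in RPKM is unresolved; the
  implementation counts depth-reconstructed reads.
- Kappa confidence intervals and multi-rater generalizations are not
  provided.
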