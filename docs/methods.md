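# Methods

## Overview

`vampscan` implements the computational side of a variant-abundance
sort-seq experiment (VAMP-seq): cells carrying single protein variants
fused to GFP are sorted into four equal-occupancy bins by their
GFP:mCherry ratio, the variants in each bin are counted by sequencing
short random barcodes, and each variant receives a normalized abundance
score. A parallel track scores short peptide tiles instead of
full-length variants to map degradation signals (degrons). Because the
package is meant to be testable without any sequencing data, it ships a
simulator that generates every intermediate product — true abundances,
barcode libraries, long reads, sorted cell pools, read counts — with
known ground truth.

## Scoring model

For barcode *b* with read frequency *f*<sub>*b,g*</sub> in gate *g*
(gates numbered 1 = lowest ratio to *G* = highest, default *G* = 4):

PSI<sub>b</sub> = Σ<sub>g</sub> *g·f*<sub>b,g</sub> / Σ<sub>g</sub> *f*<sub>b,g</sub>

Frequencies are per gate — each gate's counts divided by that gate's
total — with no pseudocounts, so PSI is invariant to per-gate
sequencing depth and bounded by [1, *G*]. Technical replicates are
merged (counts summed) *before* normalization. Barcode PSIs are
averaged per variant within each biological replicate, replicate PSIs
are averaged, and the result is rescaled to

abundance = (PSI<sub>i</sub> − PSI<sub>stop</sub>) / (PSI<sub>WT</sub> − PSI<sub>stop</sub>)

where PSI<sub>WT</sub> is the PSI of barcodes whose DNA exactly matches
the reference (a flag pools synonymous wild-type barcodes) and
PSI<sub>stop</sub> is the median PSI over nonsense variants, taken by
default across all nonsense variants after per-variant averaging (a
per-position-median alternative is provided). With this construction
the wild type scores exactly 1 and the median nonsense variant exactly
0. Per-replicate scores are also normalized within each replicate and
the reported standard deviation is taken over those; both per-replicate
PSIs and scores are emitted so the alternative convention can be
computed by the user.

The tile stability index (TSI) is the same gate-mean with tiles in
place of barcodes (no barcode layer: tiles are identified by exact
sequence match).

### Cross-library renormalization

The Odds / Evens / CT tile sub-libraries are sorted separately, so
their TSI scales drift. This is not only technical noise: because
per-gate frequencies sum to one within each pool, the read-mass-weighted
mean TSI of *any* pool is pinned at (1+…+G)/G = 2.5, so a pool's
composition shifts every member's index. Control peptides present in
every pool (a degron control near the bottom of the scale, a stabilized
variant near the top) anchor an affine map from each library onto the
reference (Odds) scale. With exactly two controls the map is the exact
interpolant — transformed controls equal the reference controls to
machine precision — and with more it is the least-squares line. The fit
must preserve orientation (positive slope); controls with equal TSI in
a library make the fit singular and raise.

## Subassembly

Long reads cover `flank – barcode(18 nt) – flank – CDS – flank`. The
barcode and CDS are located by exact flank matching: a read missing any
flank, with a flank occurring twice, or with a barcode length deviating
by more than 2 nt is rejected with a recorded reason. Variant calling
is position-wise against the reference CDS — valid without alignment
because any length difference (indel) is rejected outright, as is any
read with ≥ 10 nucleotide substitutions or more than one substituted
residue after translation. Calls are wild-type (identical DNA),
synonymous wild-type (identical protein), or the single amino-acid
variant. Per barcode, the variant with most supporting reads wins;
exact ties drop the barcode (conservative; a tie carries no evidence
either way).

## What the simulator emulates — and what it does not

**True abundances** are a two-component Gaussian mixture clipped to
[−0.05, 1.2]: a WT-like component (mean 1.0, SD 0.10) and a low
component (mean 0.0, SD 0.08). Wild-type and synonymous variants always
draw from the high component, nonsense variants from the low one, and
missense variants are low with probability 0.28 — a typical fraction of
destabilized missense variants in an abundance scan of a folded
protein.

**Sorting** maps a variant's true score affinely to a mean log10
GFP:mCherry ratio (score 1 sits one decade above score 0, i.e. a
~10-fold dynamic range) and adds per-cell log-normal noise of 0.25
decades, chosen so the WT-like and null peaks overlap modestly, as in a
real reporter distribution. Gate thresholds are the empirical quartiles
of the pooled ratio distribution, so each gate holds 25% of cells up to
integer rounding. Biological replicates redraw cell allocations;
technical replicates resample reads from the same sorted cells
(multinomial per gate at the configured depth).

**Long reads** carry per-base substitutions at a configurable rate and
at most one 1-nt indel per read. The generator does not model PCR
jackpotting, index hopping, chimeric reads, or quality scores.

**Tile pools** are constructed directly in frequency space: a linear
program finds a column-stochastic per-gate frequency matrix whose row
gate-means equal the requested TSIs exactly, with every member's read
mass within a band around its fair share and contaminant (foreign-
library) tiles holding exactly the configured read fraction. Each
library's targets are pre-distorted with the inverse of its configured
affine renormalization, so the downstream control-anchor fit recovers
exactly the configured (slope, intercept). With `depth=None` the
expected (real-valued) counts are returned — the noiseless limit used
for exactness tests; with an integer depth, counts are multinomial per
gate. Target TSIs that leave [1, G] after distortion, or pools whose
targets cannot average to the pinned pool mean, raise instead of being
silently clipped. This construction reproduces the *algebra* of sorted
pools, not their cell-level physics; it is deliberately idealized so
that recovery failures downstream indicate real pipeline defects.

Passing tests on synthetic data therefore demonstrate the pipeline's
internal consistency (formulas, filters, normalization, renormalization
and their inverses) — not robustness to artifacts absent from the
generator.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| gates | 4 | quartile sort design |
| barcode length | 18 nt | library design |
| barcodes/variant | Poisson mean 24, truncated ≥ 1 | library-scale coverage; truncation keeps every variant represented |
| substitution cutoff | ≥ 10 rejects | subassembly filter |
| tile length / step | 24 / 12 residues | degron tiling design |
| adaptors | 2 × 30 nt | cloning arms; 72-nt cores → 132-nt oligos |
| nonsense exclusion | position 1 | a stop at the initiator yields no protein; configurable |
| position-median gate | ≥ 17 scores | reporting threshold for per-position summaries |
| low-abundance cut | score < 0.5 | descriptive threshold for pathogenicity analyses |
| ROC orientation | low score ⇒ pathogenic | destabilized variants are lost to degradation; explicit flag, never auto-flipped |

Position-class thresholds (`PositionClassThresholds`) are working
defaults, not canonical values: unstable if abundance < 0.5 or ΔΔG >
2 kcal/mol; functionally constrained if stable but conservation <
−2 (the convention where more negative means less tolerated). A
position takes the strictly most common per-variant verdict;
ties or missing inputs are `unassigned`.

## Numerical choices and degenerate inputs

- Gates with zero total reads are dropped before frequency
  normalization (they carry no information for the gate-mean); barcodes
  absent from every gate are absent from the output, never zero-filled.
- PSI<sub>WT</sub> = PSI<sub>stop</sub> raises a degenerate-
  normalization error rather than producing infinities.
- Even-length tiles place their TSI at the lower-middle residue
  (residue 12 of a 24-mer starting at 1).
- Barcode-map ties are dropped, not broken arbitrarily, so the map is
  deterministic.
- All generators take an explicit seed (`numpy.random.default_rng`);
  identical seeds and parameters reproduce identical outputs, and the
  pipeline manifest records content digests to make this checkable.

## Problem sizes used in the test suite

The default simulated experiment in the tests uses a 10-residue
protein (200 variants including nonsense, WT and a synonymous marker),
~10 barcodes per variant, 100 cells per barcode, 2 biological × 2
technical replicates, and ~50 reads per barcode per gate (≥ 200 reads
per barcode overall). At this scale the scoring pipeline recovers true
abundances with Spearman ρ ≈ 0.998 and technical replicates correlate
at r > 0.99; the whole suite runs in a few seconds. Scaling the
generator up (more variants, barcodes, or depth) only tightens these
statistics.

## Known limitations

- Variant calling assumes the construct contains exactly the reference
  CDS; multi-residue variants are counted but never mapped.
- The tile simulator's LP idealizes pool composition; it cannot emulate
  the nonlinear pool-dependence of real TSI scales beyond the affine
  term the renormalization corrects.
- Clinical-label analyses (ROC) and external-score correlations consume
  user-provided tables; the package does not compute ΔΔG or
  conservation scores.
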