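# Methods

This note documents the models and procedures implemented in `cnrescan`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data benchmarks do and do not show.

## The element model

The reference element is a 32-nt consensus
(`GAAGGACAAAGAGGGGACAAAGAGGCGGAGGT`) with three named hexad half-sites at
1-based positions 3–8 (`AGGACA`), 12–17 (`AGGGGA`) and 24–29 (`GGCGGA`),
the remainder being spacer. The model is deliberately a *consensus plus
intervals*, not a position-weight matrix: every downstream rule (mismatch
counting, the retention filter, conservation classes) is defined on literal
base identity, which keeps all results exactly reproducible and auditable
against printed sequences. Alternative motifs can be supplied as a small
YAML document (consensus + hexad intervals).

## Genome scanning and the hexad retention rule

Scanning is exhaustive: every 32-nt window on both strands is compared to
the consensus by Hamming distance (vectorized over the genome; ~1 s per Mb
per strand). A window is reported when its total mismatch count is at most
`max_total_mismatches` (default 11, the largest count observed among
published viral hits; configurable). The retention rule then requires that
a hit cover consensus positions 3–29 and carry at most one mismatch per
hexad; spacer mismatches are unrestricted. Full-length hits with ≥ 4 total
mismatches (> 12% of 32) are classified *divergent*, others *conserved*.

Design choices:

- No heuristic seeding (short-word BLAST-style search) is used: for a
  32-nt query an exhaustive scan is cheap, strictly more sensitive, and
  needs no alignment statistics. Reports record the retention rule's
  outputs, not aligner scores.
- Windows truncated at sequence ends are reported (down to a 6-nt overlap,
  one hexad length) with their covered consensus range; they can pass the
  filter only when positions 3–29 are still covered. Mismatches of
  truncated windows are counted over the covered range only.
- Overlapping hits are all reported; an optional greedy reducer (fewest
  mismatches first, ties to the leftmost) is provided for counting
  occurrences in tandem arrays.
- Coordinates are 0-based half-open internally and 1-based inclusive in all
  outputs; minus-strand hits are reported in plus-strand coordinates with
  the hit sequence given in motif orientation.
- Ungapped scanning only: a handful of published hit spans are 33 nt,
  implying a gapped alignment upstream, but the printed 32-nt sequences
  reproduce the printed mismatch counts by plain Hamming distance, so a
  gapped scan mode adds nothing here and is omitted.

## Glocal alignment and the viral screen

The viral screen scores each genome by the best *query-global /
subject-local* alignment of the element: the full 32-mer must align, the
genome contributes a contiguous region, and subject bases outside the
region are free. Both element orientations are tried; ties go to the plus
strand, then the smallest start, then the shortest span. Gaps are affine: a
gap of length L costs `gap_open + L·gap_extend`. The default scheme
(match +1, mismatch −1, gap_open −5, gap_extend −2) is this package's own
choice — the upstream procedure used an aligner's unstated defaults, so
absolute scores are not comparable across implementations, only ranks and
the permutation calibration are. The scheme is configurable and echoed
into every report header.

The DP kernels are compiled with numba. The score-only kernel is batched
across queries (the inner loop runs over the query batch, which vectorizes)
and evaluates 1000 random 32-mers against a 10-kb genome in ≈ 0.2 s.
Placement reporting propagates, per DP cell, the minimum region start over
all optimal alignments reaching that cell, so the reported span is
deterministic. Aligned strings are reconstructed by a small full-traceback
global alignment on the located subject slice. The implementation is
cross-checked in the test suite against brute-force enumeration of all
gapped placements on small instances and against an independent aligner
configured for free subject end-gaps.

Null model and significance:

- 1000 iid random 32-mers (uniform base composition by default; a
  GC-matched option exists) are generated once per run and scored against
  *every* genome, so p-values are comparable across genomes.
- A hit is *significant* when its score strictly exceeds the 95th
  percentile (linear-interpolation, type-7) of its genome's null scores.
  The *p-value* is the permutation estimate `(1 + #{null ≥ obs}) / (n + 1)`;
  the +1 correction keeps p > 0 under finite resampling. Both quantities
  are reported because "exceeds 95% of the null" and "p ≤ 0.05" are not
  identical criteria at finite n.
- The full screen applies, in order: rank all genomes by best score
  (ties broken by identifier), keep the top 2000, keep the best-scoring
  genome per taxonomic family, compute p-values for the survivors, retain
  p ≤ 0.05. The order matters and is preserved exactly; the null is built
  only for the per-family survivors, which is what the p-values are
  reported for.

Calibration: across 200 seeded 10-kb null genomes with n = 1000
permutations each, the significant-call rate of the percentile rule is
0.02–0.05 depending on seed. It sits slightly below the nominal 0.05
because the observed statistic is the element's score (a fixed,
composition-biased 32-mer, maximized over two orientations) while the null
uses single-orientation uniform random 32-mers; the test suite asserts the
0.05 ± 0.03 band.

## Binding-energy hexad calling

Inputs are ΔΔG values (`ΔG(complex) − ΔG(protein) − ΔG(DNA)`, from an
upstream free-energy pipeline that this package deliberately does not
reimplement) per candidate hexad start 1..27 per receptor, as TSV. Values
are pooled across receptors (a per-receptor option exists), thresholded at
the pooled 10th percentile (type-7 linear interpolation), and starts with
ΔΔG *strictly below* the threshold are called. Per-nucleotide participation
is the count of called hexads covering each of the 32 positions.

A numerical subtlety worth knowing: with r receptors and k planted
low-energy starts per receptor, the pooled type-7 10th percentile lands at
rank `(27r − 1)/10`. For r = 3 and k = 3 this is exactly 8.0, i.e. the
percentile *equals* the largest planted value, which the strict "below"
rule then excludes — a deterministic near-miss that has nothing to do with
noise. For r ≤ 2 the interpolated percentile falls strictly inside the gap
between planted and baseline values and recovery is exact. The recovery
benchmarks therefore pool two receptors.

## Binding-curve fitting

The anisotropy of a labelled oligonucleotide titrated with protein is
modelled as a Hill isotherm on total protein concentration,
`r(c) = r_free + (r_bound − r_free)·cⁿ/(Kdⁿ + cⁿ)` — a ligand-depletion-free
approximation appropriate when probe concentration is well below Kd.
Parameters (Kd in nM, Hill coefficient n, the two anisotropy asymptotes)
are fit by Levenberg–Marquardt least squares with asymptotic standard
errors from the covariance matrix. Initial guesses: asymptotes from the
curve extremes, Kd from the half-amplitude crossing (geometric midpoint of
the bracketing concentrations), n = 1. Degenerate flat curves return a
non-convergence flag rather than raising; a fit is also rejected (flag
down, initial guess reported) if it would worsen the residual sum of
squares. Decreasing curves (r_bound < r_free) fit symmetrically with
negative amplitude.

The synthetic titration design follows the standard serial dilution, 12
log-spaced points from 2 nM to 2 mM; noise is Gaussian with standard
deviation expressed as a fraction of the binding amplitude. At 2% noise the
median relative Kd error over 100 simulated curves is ≈ 6–7%.

## Cohort statistics

Embryo cohorts are classified as atrium-only / ventricle-only / both.
Constructs are compared per category with a 2×2 chi-square (category vs
rest, construct vs construct), no continuity correction by default (the
correction is exposed as an option); an output flag marks expected cells
below 1. For the packaged wild-type (33/8/45 of 86) versus element-deletion
(9/26/24 of 59) cohorts this contrast gives χ² = 9.09, p = 0.0026 on the
atrium category — computed, not asserted, by the acceptance script.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of spec + seed (byte-identical reruns).
Planted mismatches are realized by sampling distinct positions without
replacement within the designated region (each hexad separately, then the
spacer) and resampling each base to a different nucleotide, so realized
counts equal the spec exactly and truth tables are exact. Backgrounds are
iid with configurable GC (default 0.5; 0.42 approximates a galliform
genome). Decoys: telomeric hexamer arrays `(TTAGGG)₅`, shuffled-consensus
32-mers (re-shuffled until at least one hexad carries ≥ 2 mismatches, so
they must fail the filter), and hexad violators (consensus with 2
substitutions inside one hexad).

These benchmarks establish *algorithmic* correctness — sensitivity and
specificity against known truth — not performance on real genomes: iid
backgrounds have no repeat structure, no GC isochores, no segmental
duplications, and planted copies are never nested inside repeats, so
real-genome false-positive rates cannot be read off these numbers. The
viral generator likewise plants a single copy in an iid background, whereas
real herpesvirus genomes carry strong compositional bias and terminal
repeats.

## Benchmark sizes

The standard scan benchmark plants 20 copies (cycling through clean,
spacer-only, one-per-hexad and hexad-violating mismatch classes, both
strands) and 20 decoys in 1 Mb; the screen calibration uses 200 null
genomes of 10 kb at n = 1000 permutations; the fit study uses 100
titrations. These sizes give stable statistics at desk scale — the full
acceptance run completes in about a minute on one CPU.
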