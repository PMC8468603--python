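# Methods

## The detection model

The analysis assumes a baseline-diploid genome in which aneuploidy takes
the form of large segments present in one or three copies. Sequencing
depth is proportional to copy number, so on the normalized scale
`s = (rollmed − M)/M` (M = genome-wide median per-base depth, zeros
included) the expected levels are 0, +0.5 and −0.5 for copy numbers 2, 3
and 1. Per-base depth is far too noisy to threshold directly (Poisson
noise at 100× has a coefficient of variation of 10%); the 20 kbp rolling
median suppresses both stochastic noise and short mapping artifacts
while preserving edges at the scale of interest. The median, not the
mean, of the whole genome is used for M so that the aneuploid segments
themselves do not shift the reference level as long as they are a
minority of the genome.

Region calling is deliberately simple and fully parameterized:
positions with `s > 0.35` / `s < −0.35` are candidates, runs shorter
than 1 kbp are noise, same-class runs closer than 30 kbp are one event
split by noise, and only regions spanning more than 50 kbp are reported.
The 0.35 threshold sits at the 70% point between the diploid (0) and
aneuploid (±0.5) levels, tolerating attenuation of the rolling median
near segment edges. No hidden-Markov or changepoint machinery is used —
with signal steps of ±0.5 against residual noise of a few hundredths,
thresholding the smoothed track is already near-exact, and the
parameters stay interpretable in bases and depth fractions.

### Numerical choices

- The "20 kbp" window is realized as 20001 bases so a centered window
  exists; the rolling median is an exact order-statistic computation
  (pandas' skiplist implementation), verified in tests against a
  brute-force sorted-window oracle. Positions within 10 kbp of a contig
  end are undefined, windows never span contigs, and undefined
  positions break candidate runs. An optional `stride` evaluates the
  median on a grid and holds values between grid points — documented as
  an approximation and off by default.
- Interval conventions: 1-based inclusive in memory (the `genomecov -d`
  dialect), BED 0-based half-open on disk. "Closer than 30 kbp" and
  "more than 50 kbp" are read strictly; "at least 1 kbp" is `≥`. The
  gap between runs counts the bases strictly between them.
- Merging is same-class only: a class-blind merge could fuse a triploid
  and a haploid stretch into one meaningless region. The class-blind
  variant is available behind a flag for comparison.
- Region counts are per contig; contigs that share a chromosome are not
  stitched, so event counts are upper bounds.

## Allele-balance corroboration

Copy state leaves a second, depth-independent signature: the allele
ratio at heterozygous biallelic loci. The summary statistic is the
median major-allele fraction per region. Its null (diploid) value is
*not* 0.5: at fixed depth d the major fraction is max(X, d−X)/d with
X ~ Binomial(d, 1/2), whose median at d = 100 is 0.53 by exact
enumeration (with Poisson-varying depth the simulated baseline sits
near 0.535). Testing against 0.5 would therefore flag every diploid
region. Instead the verdict uses calibrated windows: triploid-consistent
when the median falls in [0.60, 0.75] (the Binomial(d, 2/3) median is
≈ 0.667 for d ≥ 30), haploid-consistent when ≥ 0.90, diploid baseline
expected in [0.50, 0.58]. Regions with fewer than 50 loci are reported
as `insufficient` rather than judged. The windows are configurable;
their defaults are generous enough to be depth-insensitive for d ≥ 30
yet non-overlapping between states.

## Enrichment

Genes overlap a region when they share ≥ 1 base (midpoint and
full-containment rules would only shrink the selection by boundary
genes; the 1-base rule is the most inclusive and the easiest to reason
about). The test models the K genes of a category as trials that fall
in the selection with probability n/N — the orientation used by
gene-list overrepresentation services; the symmetric orientation
(n trials, probability K/N) is exposed as an option because the two are
not equivalent for small categories. p-values are exact binomial upper
tails and the correction is Bonferroni over the number of tested
categories (categories with no background gene are not tested). The
background is all annotated genes, not only genes carrying categories.

## What the simulator emulates — and what it does not

The generator reproduces the features the method depends on: ~50 contigs
with log-normally split lengths (default total 24 Mbp — the real contig
size distribution is not published, so these are order-of-magnitude
stand-ins), segmental copy-number changes, Poisson or negative-binomial
depth (the negative binomial models the overdispersion of real data;
variance = μ + μ²/size), sub-kbp single-haplotype dropout artifacts at
half depth and monoallelic read support (the mapping pathology that
defeats variant calling on highly heterozygous diploids), and
heterozygous loci at 0.05/bp (~1.2 million per 24 Mbp) whose allele
fractions follow the copy state, with the duplicated/retained haplotype
chosen once per segment so the 2:1 signal is coherent.

It does **not** simulate reads, mapping, GC or mappability bias,
position-correlated noise, repeats, or partial-population (mosaic)
aneuploidy. Passing tests therefore demonstrate that the pipeline's
logic is correct under its own statistical assumptions, not that those
assumptions hold for any particular sequencing run; on real data the
rolling median absorbs much of the unmodeled structure, but segment
boundaries and borderline (< 50 kbp, or mosaic) events inherit real-data
caveats.

Default study conditions used by the test suite and the acceptance
script: diploid depth 100× (40× in the multi-seed recovery checks —
enough that the ±0.5 signal is > 20 standard errors after smoothing),
2 Mbp contigs with 200 kbp injected segments, locus depth 100×. These
sizes keep a full suite run in minutes on one core while leaving the
law-of-large-numbers margins (±0.05 on segment means) wide.

## Passage arithmetic

Generations per transfer are log2(culture/transfer volume); totals
multiply by cycle count. Cell death is ignored, so all counts are lower
bounds. The dilution factor is reported as floor(culture/transfer),
matching the conventional "1:266" notation.

## Pipeline and plots

The orchestrated run is deterministic given its seed: simulator,
normalization, calling, allele balance and enrichment all derive their
randomness from one integer, and `report.json` round-trips byte-for-byte
across reruns. Figures follow the field's karyotype-plot conventions —
per-contig panels of 50 bp mean (blue) and 30 kbp median (red) coverage
on the normalized scale with guides at −0.5/0/+0.5, and a genome-wide
strain × contig map with triploid regions in red, haploid in blue, genes
as crosses. Plot tests assert structure (panel counts, guide levels,
shading and marker presence) rather than pixel hashes: the figures are
presentation conventions, and pixel-exact snapshots break on any
font or renderer change without catching a scientific regression.

## Known limitations

- Only copy numbers 1–3 are modeled; tetraploid-and-above segments
  would exceed the +0.5 level and be reported as triploid.
- Thresholds assume the genome is majority-diploid; a genome that is
  mostly aneuploid would drag M away from the diploid level.
- Edge attenuation of the rolling median biases region boundaries
  inward by up to half a window (10 kbp).
- The allele-balance verdicts assume a single coherent duplicated
  haplotype per segment; recombinant segments with mixed phase would
  dilute the 2:1 signal toward the diploid window.
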