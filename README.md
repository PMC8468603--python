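# covploid

Coverage-based detection of segmental aneuploidy in largely diploid
genomes, built for whole-genome sequencing of experimentally evolved
fungi such as the halotolerant black yeast *Hortaea werneckii*. Strains
that pass through hundreds of generations of serial subculture often
acquire large triploid or haploid segments; `covploid` finds them from
per-base read depth, corroborates them with allele ratios at
heterozygous loci, and asks which gene categories they are enriched for.

## Method

Given per-base depth `x_i` (the `bedtools genomecov -d` table), the
per-position score is

```
s_i = (rollmed_20kbp(x)_i − M) / M
```

where `rollmed` is the exact rolling median in a centered 20 kbp window
(computed per contig; positions without a full window are undefined) and
`M` is the median depth of the whole genome. In a majority-diploid
genome, `s ≈ 0` marks diploid sequence, `s ≈ +0.5` triploid (three
copies at 1.5× depth) and `s ≈ −0.5` haploid (one copy at 0.5× depth).
Aneuploid regions are positions with `s > 0.35` (triploid) or
`s < −0.35` (haploid) in continuous runs of at least 1 kbp, merged when
same-class runs lie closer than 30 kbp, and kept when the merged region
spans more than 50 kbp.

Calls are corroborated at heterozygous biallelic loci: the major-allele
fraction `max(a, b)/(a + b)` has median ≈ 0.53 at 100× in diploid
sequence (not 0.50 — the larger of two binomial counts is biased up),
≈ 2/3 in a triploid segment where one haplotype is duplicated, and 1.0
in a haploid segment. Gene-category overrepresentation among genes
overlapping the called regions is scored with an upper-tail binomial
test, `P(X ≥ k)` for `X ~ Binomial(K, n/N)` (K category genes, n of N
genes selected), Bonferroni-corrected.

A seeded simulator (`covploid.simgenome`) generates reference models,
strains with injected copy-number segments and sub-kbp mapping-dropout
artifacts, Poisson or negative-binomial depth, and copy-state-aware
allele counts, so the whole pipeline is testable against ground truth.
The package also includes the serial-passage bookkeeping: transferring
0.75 mL into 200 mL is a 1:266 dilution, log2(266) ≈ 8.1 generations per
cycle, ≥ 800 over 100 cycles.

## Worked example

`examples/01_simulate_and_call.py` injects a 200 kbp triploid and a
200 kbp haploid segment into a 2 Mbp contig at 100× and calls regions:

```
injected segments:
  chr1:400001-600000  copy number 3
  chr1:1200001-1400000  copy number 1

called regions (1-based, inclusive):
  chr1:401330-598666  triploid   mean score +0.495
  chr1:1200257-1399737  haploid    mean score -0.496
```

The calls bracket the truth to within ~1.5 kbp and the mean scores sit
at the triploid (+0.5) and haploid (−0.5) expectations.
`examples/02_allele_balance.py` confirms the same segments from allele
ratios (median major fraction 0.665 / 1.000, diploid baseline 0.533),
`examples/03_enrichment.py` reproduces the worked binomial value
`P(X ≥ 5) = (984/7807)^5 ≈ 3.18e-05` for a five-of-five category, and
`examples/05_full_pipeline.py` runs everything from one config, writing
`regions.bed`, `ab_report.tsv`, `enrichment.tsv`, plots and
`report.json`.

The same functionality is exposed as a CLI:

```
covploid simulate --n-contigs 1 --total-length 2000000 \
    --segment chr1:400001-600000:3 --out sim/
covploid call --depth sim/depth.tsv.gz --out regions.bed
covploid ab --loci sim/loci.tsv --regions regions.bed --out ab.tsv
covploid passage --transfer 0.75 --volume 200 --cycles 100
```

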