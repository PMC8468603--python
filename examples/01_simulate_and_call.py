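"""Simulate an aneuploid strain and recover its segments from depth alone.

Builds a 2 Mbp synthetic contig carrying a 200 kbp triploid and a 200 kbp
haploid segment, simulates Poisson sequencing depth at 100x (diploid
expectation), and calls aneuploid regions with the default thresholds
(score beyond +-0.35 in >= 1 kbp runs, merged under 30 kbp, kept over
50 kbp). The printed regions should bracket the injected segments to
within a few kbp, with mean scores near +0.5 (three copies) and -0.5
(one copy).
"""

import pandas as pd

from covploid import CnSegment, NoiseSpec, ReferenceModel, call_regions, make_strain, simulate_depth

ref = ReferenceModel(
    contigs=[("chr1", 2_000_000)],
    genes=pd.DataFrame(columns=["gene_id", "contig", "start", "end"]),
    categories={},
    het_loci=pd.DataFrame(columns=["contig", "pos"]),
)
truth = [CnSegment("chr1", 400_001, 600_000, 3), CnSegment("chr1", 1_200_001, 1_400_000, 1)]
strain = make_strain(ref, truth, n_dropouts=10, seed=1)
depth = simulate_depth(strain, NoiseSpec(base_depth=100, seed=2))

print("injected segments:")
for seg in truth:
    print(f"  {seg.contig}:{seg.start}-{seg.end}  copy number {seg.copy_number}")

regions = call_regions(depth)
print("\ncalled regions (1-based, inclusive):")
for r in regions:
    print(f"  {r.contig}:{r.start}-{r.end}  {r.cls:9s}  mean score {r.mean_score:+.3f}")
print(
    "\nA mean score of +0.5 means depth 50% above the genome median "
    "(three copies of a diploid locus); -0.5 means 50% below (one copy)."
)
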