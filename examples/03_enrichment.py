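"""Test gene categories for overrepresentation inside aneuploid regions.

Reproduces the arithmetic of a gene-list overrepresentation test: with
984 of 7807 background genes falling in triploid regions, a category
whose 5 genes are all in the selection has an upper-tail binomial
probability of (984/7807)^5 ~ 3.2e-5 before correction. Here categories
are built so that one ("CAT:hit") is concentrated in the selected set
and the rest are scattered at random.
"""

import numpy as np

from covploid import binomial_upper_tail, enrichment_table
from covploid.enrich import enrichment_frame

rng = np.random.default_rng(8)
background = {f"g{i:04d}" for i in range(7807)}
selected = set(rng.choice(sorted(background), size=984, replace=False))

categories: dict[str, set[str]] = {}
for gene in rng.choice(sorted(selected), size=5, replace=False):
    categories.setdefault(gene, set()).add("CAT:hit")  # all 5 inside regions
for gene in rng.choice(sorted(background), size=400, replace=False):
    categories.setdefault(gene, set()).add(f"CAT:null_{rng.integers(20)}")

print(f"worked value: P(X >= 5), X ~ Binomial(5, 984/7807) = "
      f"{binomial_upper_tail(5, 5, 984 / 7807):.3g}")

results = enrichment_table(categories, selected, background)
print("\ntop categories (binomial test, Bonferroni corrected):")
print(enrichment_frame(results).head(3).to_string(index=False,
      float_format=lambda v: f"{v:.3g}"))
print("\nk of K category genes selected, n of N genes selected overall; "
      "fold = k / expected; only the planted category survives correction.")
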