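"""Gene-category overrepresentation inside aneuploid regions.

A gene is "in" a selection when its interval overlaps a called region by
at least one base.  For each category with K genes in the background, the
enrichment of k selected category genes is scored with an upper-tail
binomial test: the K category genes are the trials and the genome-wide
selection fraction n/N is the success probability (the convention of
gene-list overrepresentation tools).  The symmetric orientation (n trials
at probability K/N) is available via ``orientation="selection"``.
p-values are Bonferroni-corrected by the number of tested categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ioformats import RegionSet

__all__ = [
    "EnrichmentResult",
    "genes_in_regions",
    "binomial_upper_tail",
    "enrichment_table",
    "enrichment_frame",
]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    K: int  # category genes in background
    k: int  # category genes in selection
    n: int  # selected genes
    N: int  # background genes
    expected: float  # K * n / N
    fold: float  # k / expected
    p_raw: float
    p_adj: float


def genes_in_regions(
    genes: pd.DataFrame, regions: RegionSet, class_filter: str | None = None
) -> set[str]:
    """Gene ids whose interval overlaps any (optionally class-filtered)
    region by >= 1 base.

    Union semantics across strains: pass a RegionSet holding the union of
    per-strain regions. Genes on contigs absent from the region set are
    simply unselected; that is the normal case, not an error.
    """
    selected: set[str] = set()
    use = regions.filter_class(class_filter)
    by_contig: dict[str, list] = {}
    for r in use:
        by_contig.setdefault(r.contig, []).append((r.start, r.end))
    for row in genes.itertuples(index=False):
        for start, end in by_contig.get(row.contig, ()):
            if row.start <= end and start <= row.end:
                selected.add(row.gene_id)
                break
    return selected


def binomial_upper_tail(k: int, n_trials: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n_trials, p), computed with the stable
    survival function."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if not 0 <= k <= n_trials:
        raise ValueError(f"need 0 <= k <= n_trials, got k={k}, n_trials={n_trials}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n_trials, p))


def enrichment_table(
    categories: dict[str, set[str]],
    selected: set[str],
    background: set[str],
    orientation: str = "category",
) -> list[EnrichmentResult]:
    """One enrichment row per category with >= 1 background gene.

    ``orientation="category"`` treats the K category genes as trials with
    success probability n/N; ``"selection"`` treats the n selected genes
    as trials with success probability K/N.  Rows are sorted by corrected
    p ascending, ties broken by fold descending then label.
    """
    if not background:
        raise ValueError("empty background gene set")
    if not selected <= background:
        raise ValueError("selection must be a subset of the background")
    if orientation not in ("category", "selection"):
        raise ValueError(f"unknown orientation {orientation!r}")

    N = len(background)
    n = len(selected)
    per_cat: dict[str, set[str]] = {}
    for gene, labels in categories.items():
        if gene not in background:
            continue  # unknown ids are retained in the map but ignored here
        for label in labels:
            per_cat.setdefault(label, set()).add(gene)

    tested = {label: members for label, members in per_cat.items() if members}
    m = len(tested)
    results = []
    for label, members in tested.items():
        K = len(members)
        k = len(members & selected)
        expected = K * n / N
        fold = k / expected if expected > 0 else float("nan")
        if orientation == "category":
            p_raw = binomial_upper_tail(k, K, n / N)
        else:
            p_raw = binomial_upper_tail(k, n, K / N) if n > 0 else 1.0
        results.append(
            EnrichmentResult(label, K, k, n, N, expected, fold, p_raw, min(1.0, m * p_raw))
        )
    results.sort(key=lambda r: (r.p_adj, -r.fold, r.category))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results for reporting."""
    return pd.DataFrame(
        [
            (r.category, r.K, r.k, r.n, r.N, r.expected, r.fold, r.p_raw, r.p_adj)
            for r in results
        ],
        columns=["category", "K", "k", "n", "N", "expected", "fold", "p_raw", "p_adj"],
    )
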