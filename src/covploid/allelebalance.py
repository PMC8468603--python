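"""Allele-balance corroboration of called regions.

At a heterozygous biallelic locus of a diploid the two alleles draw reads
at a 1:1 ratio; in a triploid segment the duplicated haplotype draws ~2/3
of the reads, and in a haploid segment only one haplotype remains.  The
per-region median *major*-allele fraction (the larger of the two counts
over the total) therefore separates the three states.

Note the major-allele fraction of a finite-depth diploid locus exceeds
0.5 in expectation — at 100x its median is about 0.54 — so the verdict
windows below are calibrated against the binomial distribution rather
than testing against 0.5 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ioformats import HAPLOID, TRIPLOID, AneuploidRegion, HetLocusTable, RegionSet

__all__ = [
    "VerdictWindows",
    "RegionAlleleSummary",
    "major_allele_fraction",
    "summarize_regions",
]

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class VerdictWindows:
    """Median major-allele-fraction windows that count as consistent with
    each ploidy class (and the expected diploid baseline band)."""

    triploid_lo: float = 0.60
    triploid_hi: float = 0.75
    haploid_lo: float = 0.90
    diploid_lo: float = 0.50
    diploid_hi: float = 0.58


@dataclass(frozen=True)
class RegionAlleleSummary:
    region: AneuploidRegion
    n_loci: int
    median_major_fraction: float
    baseline_major_fraction: float
    verdict: str


def major_allele_fraction(count_a: int, count_b: int) -> float:
    """max(a, b) / (a + b); symmetric in its arguments, always >= 0.5."""
    total = count_a + count_b
    if total <= 0:
        raise ValueError("zero total reads at locus")
    return max(count_a, count_b) / total


def _major_fractions(frame: pd.DataFrame) -> np.ndarray:
    a = frame["count_a"].to_numpy(dtype=float)
    b = frame["count_b"].to_numpy(dtype=float)
    return np.maximum(a, b) / (a + b)


def summarize_regions(
    loci: HetLocusTable,
    regions: RegionSet,
    min_loci: int = 50,
    windows: VerdictWindows = VerdictWindows(),
) -> list[RegionAlleleSummary]:
    """Per-region median major-allele fraction with a consistency verdict.

    A locus belongs to a region iff ``start <= pos <= end`` (1-based,
    inclusive).  The baseline is the median major fraction over loci
    outside *all* regions.  A region with fewer than ``min_loci`` loci is
    ``insufficient``; otherwise a triploid region is ``consistent`` when
    its median falls in the triploid window, a haploid region when the
    median reaches the haploid floor.
    """
    frame = loci.frame
    in_any = np.zeros(len(frame), dtype=bool)
    for r in regions:
        in_any |= (
            (frame["contig"] == r.contig) & (frame["pos"] >= r.start) & (frame["pos"] <= r.end)
        ).to_numpy()
    outside = frame[~in_any]
    baseline = float(np.median(_major_fractions(outside))) if len(outside) else float("nan")

    summaries = []
    for r in regions:
        sub = frame[
            (frame["contig"] == r.contig) & (frame["pos"] >= r.start) & (frame["pos"] <= r.end)
        ]
        n = len(sub)
        med = float(np.median(_major_fractions(sub))) if n else float("nan")
        if n < min_loci:
            verdict = INSUFFICIENT
        elif r.cls == TRIPLOID:
            verdict = CONSISTENT if windows.triploid_lo <= med <= windows.triploid_hi else INCONSISTENT
        elif r.cls == HAPLOID:
            verdict = CONSISTENT if med >= windows.haploid_lo else INCONSISTENT
        else:  # pragma: no cover - RegionSet only admits the two classes
            verdict = INCONSISTENT
        summaries.append(RegionAlleleSummary(r, n, med, baseline, verdict))
    return summaries


def summaries_frame(summaries: list[RegionAlleleSummary]) -> pd.DataFrame:
    """Tabular view of region summaries for reporting."""
    return pd.DataFrame(
        [
            (
                s.region.contig,
                s.region.start,
                s.region.end,
                s.region.cls,
                s.n_loci,
                s.median_major_fraction,
                s.baseline_major_fraction,
                s.verdict,
            )
            for s in summaries
        ],
        columns=[
            "contig",
            "start",
            "end",
            "class",
            "n_loci",
            "median_major_fraction",
            "baseline_major_fraction",
            "verdict",
        ],
    )
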