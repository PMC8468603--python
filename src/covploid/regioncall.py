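"""Aneuploid region calling: threshold -> run -> merge -> span filter.

A position is a triploid candidate when its normalized score exceeds
``hi_threshold`` (default 0.35) and a haploid candidate when it is below
``lo_threshold`` (default -0.35).  Maximal candidate runs of at least
``min_run`` bases (default 1 kbp) of the same class are merged when the
gap between them is smaller than ``max_gap`` (default 30 kbp), and merged
regions are retained only when they span more than ``min_span`` bases
(default 50 kbp, strict).

Merging never crosses contigs, and by default never crosses ploidy
classes: fusing a triploid and a haploid stretch into one region would be
biologically meaningless.  Class-blind merging is available via
``merge_across_classes`` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .depthnorm import DEFAULT_WINDOW, NormalizedTrack, genome_median, normalize, rolling_median
from .ioformats import HAPLOID, TRIPLOID, AneuploidRegion, DepthTrack, RegionSet

__all__ = ["CallParams", "Run", "candidate_runs", "merge_runs", "filter_spans", "call_regions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the region caller (all coordinates in bases)."""

    hi_threshold: float = 0.35
    lo_threshold: float = -0.35
    min_run: int = 1000
    max_gap: int = 30000
    min_span: int = 50000

    def __post_init__(self) -> None:
        if not (self.hi_threshold > 0 > self.lo_threshold):
            raise ValueError("need hi_threshold > 0 > lo_threshold")
        if self.min_run < 1 or self.max_gap < 0:
            raise ValueError("min_run must be >= 1 and max_gap >= 0")
        if self.min_span < self.min_run:
            raise ValueError("min_span must be >= min_run")


@dataclass(frozen=True)
class Run:
    """A maximal candidate stretch (1-based, inclusive)."""

    contig: str
    start: int
    end: int
    cls: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def candidate_runs(norm: NormalizedTrack, params: CallParams = CallParams()) -> list[Run]:
    """Maximal runs of positions whose score exceeds a threshold.

    Scores above ``hi_threshold`` form triploid runs, scores below
    ``lo_threshold`` haploid runs; undefined (NaN) positions break runs;
    runs shorter than ``min_run`` are discarded.
    """
    runs: list[Run] = []
    for contig, score in norm.scores.items():
        state = np.zeros(score.size, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            state[score > params.hi_threshold] = 1
            state[score < params.lo_threshold] = -1
        # boundaries of constant-state blocks
        change = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [state.size]))
        for s, e in zip(starts, ends):
            cls_code = state[s]
            if cls_code == 0 or e - s < params.min_run:
                continue
            runs.append(Run(contig, int(s) + 1, int(e), TRIPLOID if cls_code == 1 else HAPLOID))
    runs.sort(key=lambda r: (r.contig, r.start))
    return runs


def merge_runs(
    runs: list[Run], params: CallParams = CallParams(), merge_across_classes: bool = False
) -> list[Run]:
    """Transitively merge same-contig runs whose gap is smaller than
    ``max_gap``.

    The gap between consecutive runs is ``next.start - prev.end - 1``
    (bases strictly between them); "closer than" is read strictly.  Runs
    of different ploidy classes never merge unless
    ``merge_across_classes`` is set, in which case the merged run takes
    the class of its longer constituent.
    """
    merged: list[Run] = []
    key = (lambda r: r.contig) if merge_across_classes else (lambda r: (r.contig, r.cls))
    for run in sorted(runs, key=lambda r: (r.contig, r.start)):
        prev = next((m for m in reversed(merged) if key(m) == key(run)), None)
        if prev is not None and run.start - prev.end - 1 < params.max_gap:
            cls = prev.cls
            if merge_across_classes and run.span > prev.span:
                cls = run.cls
            merged[merged.index(prev)] = Run(prev.contig, prev.start, max(prev.end, run.end), cls)
        else:
            merged.append(run)
    merged.sort(key=lambda r: (r.contig, r.start))
    return merged


def filter_spans(
    merged: list[Run],
    params: CallParams = CallParams(),
    norm: NormalizedTrack | None = None,
) -> RegionSet:
    """Retain regions spanning strictly more than ``min_span`` bases and
    attach the mean defined score (NaN when no track is supplied)."""
    regions = []
    for run in merged:
        if run.span <= params.min_span:
            continue
        score = norm.mean_score(run.contig, run.start, run.end) if norm is not None else float("nan")
        regions.append(AneuploidRegion(run.contig, run.start, run.end, run.cls, score))
    return RegionSet(regions)


def call_regions(
    depth: DepthTrack,
    params: CallParams = CallParams(),
    window: int = DEFAULT_WINDOW,
    merge_across_classes: bool = False,
) -> RegionSet:
    """Full caller: rolling median -> genome-median normalization ->
    thresholded runs -> gap merge -> span filter."""
    norm = normalize(rolling_median(depth, window=window), genome_median(depth))
    runs = candidate_runs(norm, params)
    merged = merge_runs(runs, params, merge_across_classes=merge_across_classes)
    regions = filter_spans(merged, params, norm)
    logger.info(
        "call_regions: %d candidate runs -> %d merged -> %d regions",
        len(runs), len(merged), len(regions),
    )
    return regions
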