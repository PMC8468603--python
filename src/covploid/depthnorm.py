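"""Rolling-median depth normalization and binned coverage summaries.

The normalized score at a position is ``(rollmed - M) / M`` where
``rollmed`` is the exact median of per-base depth in a centered window
(default 20001 bp, the odd realization of a 20 kbp window) and ``M`` is
the median per-base depth of the whole genome, zeros included.  In a
largely diploid genome the score sits near 0 in diploid regions, near
+0.5 in triploid regions and near -0.5 in haploid regions.

Positions where the centered window does not fit inside the contig are
undefined (NaN); contigs shorter than the window are entirely undefined.
Windows never cross contig boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import DepthTrack

__all__ = [
    "NormalizedTrack",
    "genome_median",
    "rolling_median",
    "normalize",
    "bin_mean",
    "bin_median",
]

DEFAULT_WINDOW = 20001


@dataclass
class NormalizedTrack:
    """Per-contig arrays of normalized rolling-median scores; undefined
    positions are NaN."""

    scores: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def contigs(self) -> list[str]:
        return list(self.scores)

    def defined_mask(self, contig: str) -> np.ndarray:
        return ~np.isnan(self.scores[contig])

    def mean_score(self, contig: str, start: int, end: int) -> float:
        """Mean of defined scores over a 1-based inclusive interval."""
        window = self.scores[contig][start - 1 : end]
        if np.all(np.isnan(window)):
            return float("nan")
        return float(np.nanmean(window))


def genome_median(track: DepthTrack) -> float:
    """Median per-base depth over all contigs, zero-depth positions
    included (an even count averages the central pair)."""
    if not track.depths:
        raise ValueError("empty depth track")
    return float(np.median(np.concatenate(list(track.depths.values()))))


def rolling_median(
    track: DepthTrack, window: int = DEFAULT_WINDOW, stride: int = 1
) -> dict[str, np.ndarray]:
    """Exact centered rolling median of depth, per contig.

    Positions closer than ``(window - 1) / 2`` to either contig end are
    NaN.  ``stride > 1`` evaluates the median only every ``stride``-th
    position and holds the value across the block — a documented
    approximation for speed; the default ``stride=1`` is exact everywhere.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    half = (window - 1) // 2
    out: dict[str, np.ndarray] = {}
    for contig, depth in track.depths.items():
        n = depth.size
        if n < window:
            out[contig] = np.full(n, np.nan)
            continue
        if stride == 1:
            med = (
                pd.Series(depth)
                .rolling(window, center=True, min_periods=window)
                .median()
                .to_numpy()
            )
        else:
            med = np.full(n, np.nan)
            centers = np.arange(half, n - half, stride)
            vals = np.array([np.median(depth[c - half : c + half + 1]) for c in centers])
            for c, v in zip(centers, vals):
                med[c : min(c + stride, n - half)] = v
        out[contig] = med
    return out


def normalize(rollmed: dict[str, np.ndarray], median_depth: float) -> NormalizedTrack:
    """Score each position as ``(x - M) / M``; NaN propagates."""
    if median_depth <= 0:
        raise ValueError(f"genome median depth must be positive, got {median_depth}")
    return NormalizedTrack(
        {c: (arr - median_depth) / median_depth for c, arr in rollmed.items()}
    )


def _binned(arr: np.ndarray, width: int, reducer) -> np.ndarray:
    n_bins = -(-arr.size // width)
    return np.array([reducer(arr[i * width : (i + 1) * width]) for i in range(n_bins)])


def bin_mean(track: DepthTrack, width: int = 50) -> dict[str, np.ndarray]:
    """Arithmetic mean depth in left-aligned non-overlapping bins; the
    final partial bin is averaged over its actual length."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    return {c: _binned(a, width, np.mean) for c, a in track.depths.items()}


def bin_median(track: DepthTrack, width: int = 30000) -> dict[str, np.ndarray]:
    """Median depth in left-aligned non-overlapping bins."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    return {c: _binned(a, width, np.median) for c, a in track.depths.items()}
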