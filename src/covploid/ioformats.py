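"""On-disk formats and validated in-memory containers.

Coordinate conventions
----------------------
In memory everything is 1-based, inclusive — the convention of
``bedtools genomecov -d`` output, which is the canonical depth input.
Region files on disk are BED (0-based, half-open); the shift happens
only in :func:`write_regions_bed` / :func:`read_regions_bed`.

Depth files may be gzip-compressed; compression is detected from the
``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "HetLocusTable",
    "AneuploidRegion",
    "RegionSet",
    "FormatError",
    "read_depth",
    "write_depth",
    "read_regions_bed",
    "write_regions_bed",
    "read_genes",
    "read_categories",
    "read_allele_counts",
    "write_allele_counts",
]

TRIPLOID = "triploid"
HAPLOID = "haploid"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# DepthTrack


@dataclass
class DepthTrack:
    """Per-base sequencing depth, one integer array per contig.

    ``depths[contig][i]`` is the depth at 1-based position ``i + 1``.
    """

    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"contig {contig!r}: depth array must be 1-D and non-empty")
            if np.any(arr < 0):
                raise ValueError(f"contig {contig!r}: negative depth")
            self.depths[contig] = arr.astype(np.int64, copy=False)

    @property
    def contigs(self) -> list[str]:
        return list(self.depths)

    def length(self, contig: str) -> int:
        return int(self.depths[contig].size)

    @property
    def total_length(self) -> int:
        return sum(a.size for a in self.depths.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        return self.contigs == other.contigs and all(
            np.array_equal(self.depths[c], other.depths[c]) for c in self.depths
        )


def read_depth(path: str | Path) -> DepthTrack:
    """Read a three-column ``genomecov -d`` style table (contig, 1-based
    position, depth).

    Positions within each contig must be contiguous and ascending from 1;
    a gap, a non-monotone position, or a negative depth raises
    :class:`FormatError` naming the contig and line.
    """
    depths: dict[str, list[int]] = {}
    current: str | None = None
    expected_pos = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
            contig, pos_s, depth_s = parts
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer position or depth") from exc
            if depth < 0:
                raise FormatError(f"line {lineno}, contig {contig!r}: negative depth {depth}")
            if contig != current:
                if contig in depths:
                    raise FormatError(f"line {lineno}: contig {contig!r} appears in non-contiguous blocks")
                depths[contig] = []
                current = contig
                expected_pos = 1
            if pos != expected_pos:
                raise FormatError(
                    f"line {lineno}, contig {contig!r}: position {pos}, expected {expected_pos} "
                    f"(gap or non-monotone positions)"
                )
            depths[contig].append(depth)
            expected_pos += 1
    if not depths:
        raise FormatError(f"{path}: empty depth file")
    return DepthTrack({c: np.asarray(v, dtype=np.int64) for c, v in depths.items()})


def write_depth(track: DepthTrack, path: str | Path) -> None:
    """Write a DepthTrack in ``genomecov -d`` dialect (round-trips with
    :func:`read_depth`)."""
    with _open_text(path, "wt") as fh:
        for contig, arr in track.depths.items():
            frame = pd.DataFrame(
                {"contig": contig, "pos": np.arange(1, arr.size + 1), "depth": arr}
            )
            frame.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# HetLocusTable


@dataclass
class HetLocusTable:
    """Heterozygous biallelic loci with read counts for the two alleles.

    Backed by a DataFrame with columns ``contig, pos, count_a, count_b``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["contig", "pos", "count_a", "count_b"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"HetLocusTable missing columns: {missing}")
        f = self.frame
        if (f["count_a"] < 0).any() or (f["count_b"] < 0).any():
            raise ValueError("negative allele counts")
        if ((f["count_a"] + f["count_b"]) <= 0).any():
            raise ValueError("locus with zero total reads")
        if f.duplicated(subset=["contig", "pos"]).any():
            raise ValueError("duplicate (contig, position) rows")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


def read_allele_counts(path: str | Path) -> HetLocusTable:
    """Read a 4-column TSV: contig, 1-based position, allele-A reads,
    allele-B reads."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer field") from exc
    frame = pd.DataFrame(rows, columns=["contig", "pos", "count_a", "count_b"])
    try:
        return HetLocusTable(frame)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_allele_counts(table: HetLocusTable, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        table.frame.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class AneuploidRegion:
    """A contig interval (1-based, inclusive) with its ploidy class and
    mean normalized depth score."""

    contig: str
    start: int
    end: int
    cls: str
    mean_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.cls not in (TRIPLOID, HAPLOID):
            raise ValueError(f"unknown ploidy class {self.cls!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class RegionSet:
    """An ordered collection of aneuploid regions.

    Regions of the same contig and class must not overlap.
    """

    def __init__(self, regions: Iterator[AneuploidRegion] | list[AneuploidRegion] = ()):
        self.regions: list[AneuploidRegion] = sorted(
            regions, key=lambda r: (r.contig, r.start, r.end)
        )
        seen: dict[tuple[str, str], int] = {}
        for r in self.regions:
            key = (r.contig, r.cls)
            if key in seen and r.start <= seen[key]:
                raise ValueError(f"overlapping {r.cls} regions on {r.contig}")
            seen[key] = max(seen.get(key, 0), r.end)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[AneuploidRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> AneuploidRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def filter_class(self, cls: str | None) -> "RegionSet":
        if cls is None:
            return self
        return RegionSet([r for r in self.regions if r.cls == cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.contig, r.start, r.end, r.cls, r.mean_score) for r in self.regions],
            columns=["contig", "start", "end", "class", "mean_score"],
        )


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """Write regions as BED6: 0-based half-open coordinates, ploidy class
    in the name column, mean score ×1000 clamped to [0, 1000] in the score
    column."""
    with _open_text(path, "wt") as fh:
        for r in regions:
            score = 0 if np.isnan(r.mean_score) else int(round(min(max(r.mean_score * 1000, 0), 1000)))
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.cls}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    """Read back a BED file written by :func:`write_regions_bed`."""
    regions = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: expected ≥4 BED fields")
            contig, start0, end0, cls = parts[:4]
            score = float(parts[4]) / 1000 if len(parts) > 4 else float("nan")
            try:
                regions.append(AneuploidRegion(contig, int(start0) + 1, int(end0), cls, score))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# Genes and categories


def read_genes(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Read a gene table as a DataFrame with columns
    ``gene_id, contig, start, end`` (1-based, inclusive).

    Two dialects are accepted: a 4-column TSV ``gene_id, contig, start,
    end``, or GFF3 (detected by the ``.gff``/``.gff3`` suffix or a
    ``##gff-version`` header), from which features of ``feature_type`` are
    taken and the gene id parsed from the ``ID=`` attribute.
    """
    path = Path(path)
    is_gff = path.suffix.lower().lstrip(".").rstrip("3").endswith("gff") or _peek_gff(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_gff:
                if len(parts) != 9:
                    raise FormatError(f"line {lineno}: expected 9 GFF3 fields, got {len(parts)}")
                if parts[2] != feature_type:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise FormatError(f"line {lineno}: {feature_type} feature without ID attribute")
                rows.append((gene_id, parts[0], int(parts[3]), int(parts[4])))
            else:
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: expected 4 fields, got {len(parts)}")
                try:
                    rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer coordinate") from exc
    frame = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"])
    if (frame["start"] > frame["end"]).any():
        bad = frame.loc[frame["start"] > frame["end"], "gene_id"].iloc[0]
        raise FormatError(f"gene {bad!r}: start > end")
    if frame["gene_id"].duplicated().any():
        dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r}")
    return frame


def _peek_gff(path: Path) -> bool:
    try:
        with _open_text(path) as fh:
            first = fh.readline()
        return first.startswith("##gff-version")
    except OSError:
        return False


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        genes[["gene_id", "contig", "start", "end"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


def read_categories(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV ``gene_id, category`` into a gene → categories
    map. A gene may appear on several lines (one per category)."""
    cats: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 fields, got {len(parts)}")
            cats.setdefault(parts[0], set()).add(parts[1])
    return cats


def write_categories(cats: dict[str, set[str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gene in sorted(cats):
            for label in sorted(cats[gene]):
                fh.write(f"{gene}\t{label}\n")
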