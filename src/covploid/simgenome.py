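"""Synthetic references, aneuploid strains, depth tracks and allele counts.

The generator emulates the statistical structure the downstream analysis
assumes: a largely diploid genome in ~50 contigs, injected copy-number-3
(triploid, 1.5x expected depth) and copy-number-1 (haploid, 0.5x expected
depth) segments, Poisson or negative-binomial per-base depth noise, short
(<1 kbp) mapping-dropout artifacts where only one haplotype maps, and
heterozygous biallelic loci whose allele fractions track the copy state
(1/2 diploid, 2/3 triploid, monoallelic haploid).

All randomness flows from a single seeded :class:`numpy.random.Generator`;
there is no global state, and every output is bit-identical for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import DepthTrack, HetLocusTable

__all__ = [
    "ReferenceModel",
    "StrainModel",
    "NoiseSpec",
    "CnSegment",
    "make_reference",
    "make_strain",
    "simulate_depth",
    "simulate_allele_counts",
]


@dataclass(frozen=True)
class CnSegment:
    """A copy-number segment, 1-based inclusive coordinates."""

    contig: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid segment interval [{self.start}, {self.end}]")
        if self.copy_number not in (1, 2, 3):
            raise ValueError(f"copy number must be 1, 2 or 3, got {self.copy_number}")


@dataclass
class ReferenceModel:
    """A reference genome model: contigs, genes, gene categories, and
    heterozygous biallelic loci."""

    contigs: list[tuple[str, int]]
    genes: pd.DataFrame  # gene_id, contig, start, end
    categories: dict[str, set[str]]
    het_loci: pd.DataFrame  # contig, pos

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        if len(lengths) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        if any(length <= 0 for length in lengths.values()):
            raise ValueError("contig lengths must be positive")
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        for _, row in g.iterrows():
            if row.contig not in lengths:
                raise ValueError(f"gene {row.gene_id!r} on unknown contig {row.contig!r}")
            if not (1 <= row.start <= row.end <= lengths[row.contig]):
                raise ValueError(f"gene {row.gene_id!r} outside contig bounds")
        h = self.het_loci
        for contig, sub in h.groupby("contig", sort=False):
            if contig not in lengths:
                raise ValueError(f"het locus on unknown contig {contig!r}")
            if (sub["pos"] < 1).any() or (sub["pos"] > lengths[contig]).any():
                raise ValueError(f"het locus outside contig {contig!r}")

    def contig_length(self, contig: str) -> int:
        return dict(self.contigs)[contig]


@dataclass
class StrainModel:
    """A strain: a reference plus its copy-number segments and short
    single-haplotype mapping-dropout artifacts.

    Positions not covered by a segment have copy number 2.
    """

    reference: ReferenceModel
    cn_segments: list[CnSegment] = field(default_factory=list)
    dropout_artifacts: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.reference.contigs)
        by_contig: dict[str, list[CnSegment]] = {}
        for seg in self.cn_segments:
            if seg.contig not in lengths:
                raise ValueError(f"segment on unknown contig {seg.contig!r}")
            if seg.end > lengths[seg.contig]:
                raise ValueError(f"segment exceeds contig {seg.contig!r} length")
            by_contig.setdefault(seg.contig, []).append(seg)
        for contig, segs in by_contig.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping segments on contig {contig!r}")
        for contig, start, end in self.dropout_artifacts:
            if contig not in lengths or not (1 <= start <= end <= lengths[contig]):
                raise ValueError("dropout artifact outside contig bounds")
            if end - start + 1 >= 1000:
                raise ValueError("dropout artifacts must be shorter than 1 kbp")

    def copy_number(self, contig: str, pos: int) -> int:
        for seg in self.cn_segments:
            if seg.contig == contig and seg.start <= pos <= seg.end:
                return seg.copy_number
        return 2

    def copy_number_array(self, contig: str) -> np.ndarray:
        """Per-base copy number for one contig (index 0 = position 1)."""
        arr = np.full(self.reference.contig_length(contig), 2, dtype=np.int8)
        for seg in self.cn_segments:
            if seg.contig == contig:
                arr[seg.start - 1 : seg.end] = seg.copy_number
        return arr


@dataclass(frozen=True)
class NoiseSpec:
    """Depth-noise model: expected per-base depth of a diploid position and
    the count distribution family.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mean + mean^2 / dispersion); ignored for Poisson.
    """

    base_depth: float
    family: str = "poisson"
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "negative_binomial" and (self.dispersion is None or self.dispersion <= 0):
            raise ValueError("negative_binomial requires positive dispersion")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.family == "poisson":
        return rng.poisson(mean)
    size = noise.dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def make_reference(
    n_contigs: int = 50,
    total_length: int = 24_000_000,
    gene_density: float = 325.0,
    het_density: float = 0.05,
    n_categories: int = 40,
    seed: int = 0,
    length_sigma: float = 0.7,
) -> ReferenceModel:
    """Generate a synthetic reference model.

    Parameters
    ----------
    n_contigs:
        Number of contigs; the contig count of the analysed genome's
        largest contigs is the scale default.
    total_length:
        Total genome size in bases, split log-normally across contigs
        (``length_sigma`` controls size heterogeneity).
    gene_density:
        Genes per Mbp; the default corresponds to ~7800 genes on 24 Mbp.
    het_density:
        Heterozygous biallelic loci per base; the default of 0.05/bp gives
        ~1.2 million loci on 24 Mbp, matching the scale of a highly
        heterozygous diploid mapped to a haploid reference.
    n_categories:
        Number of functional category labels to distribute over genes.
    """
    if n_contigs <= 0 or total_length <= 0 or gene_density <= 0 or n_categories <= 0:
        raise ValueError("all counts and densities must be positive")
    if het_density < 0:
        raise ValueError("het_density must be non-negative")
    rng = np.random.default_rng(seed)

    raw = rng.lognormal(mean=0.0, sigma=length_sigma, size=n_contigs)
    lengths = np.maximum((raw / raw.sum() * total_length).astype(np.int64), 1000)
    order = np.argsort(-lengths)
    contigs = [(f"contig_{i + 1:03d}", int(lengths[j])) for i, j in enumerate(order)]

    gene_rows = []
    gene_counter = 0
    for contig, length in contigs:
        n_genes = int(round(gene_density * length / 1e6))
        if n_genes == 0:
            continue
        # one gene per equal-width slot: non-overlap by construction
        slot = length / n_genes
        for k in range(n_genes):
            lo = int(k * slot) + 1
            hi = int((k + 1) * slot)
            gene_len = min(int(rng.integers(500, 3000)), hi - lo)
            start = int(rng.integers(lo, hi - gene_len + 1)) if hi - gene_len > lo else lo
            gene_counter += 1
            gene_rows.append((f"g{gene_counter:05d}", contig, start, start + gene_len))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "contig", "start", "end"])

    labels = [f"CAT:{i + 1:03d}" for i in range(n_categories)]
    categories: dict[str, set[str]] = {}
    n_per_gene = rng.poisson(0.8, size=len(genes))
    for gene_id, k in zip(genes["gene_id"], n_per_gene):
        if k > 0:
            picks = rng.choice(n_categories, size=min(k, n_categories), replace=False)
            categories[gene_id] = {labels[i] for i in picks}

    het_rows = []
    for contig, length in contigs:
        n_loci = rng.binomial(length, min(het_density, 1.0)) if het_density > 0 else 0
        if n_loci:
            pos = np.sort(rng.choice(length, size=n_loci, replace=False)) + 1
            het_rows.append(pd.DataFrame({"contig": contig, "pos": pos}))
    het_loci = (
        pd.concat(het_rows, ignore_index=True)
        if het_rows
        else pd.DataFrame({"contig": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    )

    return ReferenceModel(contigs, genes, categories, het_loci)


def make_strain(
    ref: ReferenceModel,
    segments: list[CnSegment] | list[tuple[str, int, int, int]] = (),
    n_dropouts: int = 0,
    seed: int = 0,
) -> StrainModel:
    """Build a strain with the requested copy-number segments plus
    ``n_dropouts`` short dropout artifacts placed uniformly outside the
    requested segments.

    Artifact lengths are drawn uniformly in 100-900 bp, deliberately below
    the 1 kbp run rule of the region caller.
    """
    segs = [s if isinstance(s, CnSegment) else CnSegment(*s) for s in segments]
    rng = np.random.default_rng(seed)
    lengths = dict(ref.contigs)
    names = list(lengths)
    sizes = np.array([lengths[c] for c in names], dtype=float)
    dropouts: list[tuple[str, int, int]] = []
    attempts = 0
    while len(dropouts) < n_dropouts:
        attempts += 1
        if attempts > 1000 * max(n_dropouts, 1):
            raise RuntimeError("could not place dropout artifacts outside segments")
        contig = names[rng.choice(len(names), p=sizes / sizes.sum())]
        size = int(rng.integers(100, 900, endpoint=True))
        if lengths[contig] <= size:
            continue
        start = int(rng.integers(1, lengths[contig] - size + 1))
        end = start + size - 1
        if any(s.contig == contig and s.start <= end and start <= s.end for s in segs):
            continue
        if any(c == contig and a <= end and start <= b for c, a, b in dropouts):
            continue
        dropouts.append((contig, start, end))
    return StrainModel(ref, segs, dropouts)


def simulate_depth(strain: StrainModel, noise: NoiseSpec) -> DepthTrack:
    """Simulate a per-base depth track.

    Expected depth at each base is ``base_depth * copy_number / 2``;
    inside a dropout artifact only one haplotype maps, halving the
    expectation again.
    """
    rng = np.random.default_rng(noise.seed)
    depths: dict[str, np.ndarray] = {}
    for contig, _length in strain.reference.contigs:
        cn = strain.copy_number_array(contig)
        mean = noise.base_depth * cn.astype(float) / 2.0
        for c, a, b in strain.dropout_artifacts:
            if c == contig:
                mean[a - 1 : b] *= 0.5
        depths[contig] = _draw_counts(rng, mean, noise)
    return DepthTrack(depths)


def simulate_allele_counts(
    strain: StrainModel, depth_at_locus: float, seed: int = 0
) -> HetLocusTable:
    """Simulate allele read counts at the reference's heterozygous loci.

    Total reads per locus are Poisson with mean ``depth_at_locus * cn/2``;
    allele-A reads are Binomial(total, p) with p = 1/2 at diploid loci,
    2/3 or 1/3 at triploid loci (which haplotype is duplicated is fixed
    once per segment), and 0 or 1 at haploid loci (which haplotype is
    retained is fixed per segment). Loci inside dropout artifacts look
    monoallelic, the signature of single-subgenome mapping. Loci whose
    drawn total is zero are omitted.
    """
    if depth_at_locus <= 0:
        raise ValueError("depth_at_locus must be positive")
    rng = np.random.default_rng(seed)
    ref = strain.reference

    # per-segment haplotype choice: True = haplotype A duplicated/retained
    hap_a: dict[CnSegment, bool] = {
        seg: bool(rng.integers(0, 2)) for seg in strain.cn_segments if seg.copy_number != 2
    }

    rows = []
    for contig, sub in ref.het_loci.groupby("contig", sort=False):
        positions = sub["pos"].to_numpy()
        cn = strain.copy_number_array(contig)[positions - 1]
        p = np.full(positions.size, 0.5)
        for seg in strain.cn_segments:
            if seg.contig != contig or seg.copy_number == 2:
                continue
            inside = (positions >= seg.start) & (positions <= seg.end)
            if seg.copy_number == 3:
                p[inside] = 2 / 3 if hap_a[seg] else 1 / 3
            else:
                p[inside] = 1.0 if hap_a[seg] else 0.0
        dropout_mono = np.zeros(positions.size, dtype=bool)
        for c, a, b in strain.dropout_artifacts:
            if c == contig:
                dropout_mono |= (positions >= a) & (positions <= b)
        mean = depth_at_locus * cn.astype(float) / 2.0
        mean[dropout_mono] *= 0.5
        p[dropout_mono] = 1.0
        total = rng.poisson(mean)
        count_a = rng.binomial(total, p)
        keep = total > 0
        rows.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": positions[keep],
                    "count_a": count_a[keep],
                    "count_b": (total - count_a)[keep],
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["contig", "pos", "count_a", "count_b"])
    )
    return HetLocusTable(frame)
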