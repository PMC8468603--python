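"""End-to-end orchestration: simulate or load -> normalize -> call ->
allele balance -> enrichment, with karyotype-style plots and a
machine-readable run report.

A run is configured by a :class:`RunConfig`, either from real input files
(depth table, allele counts, genes, categories) or from simulator
parameters — exactly one of the two.  Given a seed, a run is
deterministic: rerunning the same configuration reproduces every output
byte (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelebalance import VerdictWindows, summaries_frame, summarize_regions
from .depthnorm import DEFAULT_WINDOW, NormalizedTrack, bin_mean, bin_median, genome_median, normalize, rolling_median
from .enrich import enrichment_frame, enrichment_table, genes_in_regions
from .ioformats import (
    HAPLOID,
    TRIPLOID,
    DepthTrack,
    HetLocusTable,
    RegionSet,
    read_allele_counts,
    read_categories,
    read_depth,
    read_genes,
    write_allele_counts,
    write_depth,
    write_regions_bed,
)
from .regioncall import CallParams, candidate_runs, filter_spans, merge_runs
from .simgenome import CnSegment, NoiseSpec, make_reference, make_strain, simulate_allele_counts, simulate_depth

__all__ = ["RunConfig", "RunReport", "run", "coverage_plot", "region_map_plot"]

logger = logging.getLogger(__name__)

CLS_COLOR = {TRIPLOID: "#d62728", HAPLOID: "#1f77b4"}


@dataclass
class SimSpec:
    """Simulator half of a run configuration."""

    n_contigs: int = 5
    total_length: int = 3_000_000
    gene_density: float = 325.0
    het_density: float = 0.002
    n_categories: int = 20
    segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    n_dropouts: int = 0
    base_depth: float = 100.0
    family: str = "poisson"
    dispersion: float | None = None
    depth_at_locus: float = 100.0


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` (simulator parameters) or ``depth_path`` (real
    inputs) must be present.
    """

    outdir: str | Path = "covploid_out"
    seed: int = 0
    sim: SimSpec | None = None
    depth_path: str | Path | None = None
    loci_path: str | Path | None = None
    genes_path: str | Path | None = None
    categories_path: str | Path | None = None
    params: CallParams = field(default_factory=CallParams)
    window: int = DEFAULT_WINDOW
    ab_windows: VerdictWindows = field(default_factory=VerdictWindows)
    ab_min_loci: int = 50
    enrich_class: str | None = None
    enrich_orientation: str = "category"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.depth_path is None):
            raise ValueError("exactly one of simulator spec or depth_path must be given")
        for p in (self.depth_path, self.loci_path, self.genes_path, self.categories_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "sim" in raw:
            sim_raw = dict(raw.pop("sim"))
            sim_raw["segments"] = [tuple(s) for s in sim_raw.get("segments", [])]
            kwargs["sim"] = SimSpec(**sim_raw)
        if "params" in raw:
            kwargs["params"] = CallParams(**raw.pop("params"))
        if "ab_windows" in raw:
            kwargs["ab_windows"] = VerdictWindows(**raw.pop("ab_windows"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    genome_median_depth: float
    n_candidate_runs: int
    n_merged_runs: int
    n_regions: dict[str, int]
    regions: list[dict[str, Any]]
    allele_balance: list[dict[str, Any]]
    n_selected_genes: int
    n_background_genes: int
    top_enrichment: list[dict[str, Any]]
    provenance: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_norm_tsv(
    depth: DepthTrack, rollmed: dict[str, np.ndarray], norm: NormalizedTrack, path: Path
) -> None:
    frames = []
    for contig, raw in depth.depths.items():
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": np.arange(1, raw.size + 1),
                    "raw": raw,
                    "rollmed": rollmed[contig],
                    "score": norm.scores[contig],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all outputs into
    ``config.outdir``.  Returns the run report (also written as
    ``report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.sim is not None:
            s = config.sim
            ref = make_reference(
                n_contigs=s.n_contigs,
                total_length=s.total_length,
                gene_density=s.gene_density,
                het_density=s.het_density,
                n_categories=s.n_categories,
                seed=config.seed,
            )
            strain = make_strain(
                ref, [CnSegment(*t) for t in s.segments], s.n_dropouts, seed=config.seed + 1
            )
            noise = NoiseSpec(s.base_depth, s.family, s.dispersion, seed=config.seed + 2)
            depth = simulate_depth(strain, noise)
            loci = simulate_allele_counts(strain, s.depth_at_locus, seed=config.seed + 3)
            genes = ref.genes
            categories = ref.categories
            write_depth(depth, outdir / "depth.tsv.gz")
            write_allele_counts(loci, outdir / "loci.tsv")
            truth = RegionSet(
                [
                    # truth labels reuse the region container; cn->class
                    _truth_region(t)
                    for t in s.segments
                    if t[3] != 2
                ]
            )
            write_regions_bed(truth, outdir / "truth_segments.bed")
        else:
            depth = read_depth(config.depth_path)
            loci = read_allele_counts(config.loci_path) if config.loci_path else None
            genes = read_genes(config.genes_path) if config.genes_path else None
            categories = read_categories(config.categories_path) if config.categories_path else {}
        logger.info("stage=input contigs=%d total_bp=%d", len(depth.contigs), depth.total_length)

        stage = "normalize"
        median_depth = genome_median(depth)
        rollmed = rolling_median(depth, window=config.window)
        norm = normalize(rollmed, median_depth)
        _write_norm_tsv(depth, rollmed, norm, outdir / "norm.tsv")
        logger.info("stage=normalize genome_median=%s", median_depth)

        stage = "call"
        runs = candidate_runs(norm, config.params)
        merged = merge_runs(runs, config.params)
        regions = filter_spans(merged, config.params, norm)
        write_regions_bed(regions, outdir / "regions.bed")
        logger.info(
            "stage=call runs=%d merged=%d regions=%d", len(runs), len(merged), len(regions)
        )

        stage = "allele_balance"
        ab_rows: list[dict[str, Any]] = []
        if loci is not None:
            summaries = summarize_regions(loci, regions, config.ab_min_loci, config.ab_windows)
            ab_frame = summaries_frame(summaries)
            ab_frame.to_csv(outdir / "ab_report.tsv", sep="\t", index=False)
            ab_rows = ab_frame.to_dict("records")
        logger.info("stage=allele_balance regions_summarized=%d", len(ab_rows))

        stage = "enrichment"
        selected: set[str] = set()
        background: set[str] = set()
        top: list[dict[str, Any]] = []
        if genes is not None:
            background = set(genes["gene_id"])
            selected = genes_in_regions(genes, regions, config.enrich_class)
            if categories and selected:
                results = enrichment_table(
                    categories, selected, background, config.enrich_orientation
                )
                eframe = enrichment_frame(results)
                eframe.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                top = eframe.head(10).to_dict("records")
        logger.info("stage=enrichment selected=%d background=%d", len(selected), len(background))

        stage = "plot"
        if config.make_plots:
            coverage_plot(depth, norm, regions, path=outdir / "coverage.png")
            if genes is not None:
                region_map_plot(
                    {"strain": regions},
                    [(c, depth.length(c)) for c in depth.contigs],
                    genes=genes,
                    path=outdir / "region_map.png",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = RunReport(
        genome_median_depth=median_depth,
        n_candidate_runs=len(runs),
        n_merged_runs=len(merged),
        n_regions={
            TRIPLOID: sum(r.cls == TRIPLOID for r in regions),
            HAPLOID: sum(r.cls == HAPLOID for r in regions),
        },
        regions=regions.to_frame().to_dict("records"),
        allele_balance=ab_rows,
        n_selected_genes=len(selected),
        n_background_genes=len(background),
        top_enrichment=top,
        provenance={
            "seed": config.seed,
            "window": config.window,
            "params": dataclasses.asdict(config.params),
            "version": __version__,
        },
    )
    report.to_json(outdir / "report.json")
    return report


def _truth_region(t: tuple[str, int, int, int]):
    from .ioformats import AneuploidRegion

    contig, start, end, cn = t
    return AneuploidRegion(contig, start, end, TRIPLOID if cn == 3 else HAPLOID, 0.5 * (cn - 2))


# ---------------------------------------------------------------------------
# Plots


def coverage_plot(
    depth: DepthTrack,
    norm: NormalizedTrack,
    regions: RegionSet,
    top_n_contigs: int = 50,
    mean_bin: int = 50,
    median_bin: int = 30000,
    path: str | Path | None = None,
) -> plt.Figure:
    """Per-contig coverage panels on the normalized scale.

    Blue: arithmetic mean depth in ``mean_bin`` bp bins; red: median
    depth in ``median_bin`` bp bins — both shown as (value - M)/M where M
    is the genome median depth.  Horizontal guides mark -0.5, 0 and 0.5
    (the haploid, diploid and triploid expectations); called regions are
    shaded by class.
    """
    median_depth = genome_median(depth)
    contigs = sorted(depth.contigs, key=depth.length, reverse=True)[:top_n_contigs]
    means = bin_mean(depth, mean_bin)
    medians = bin_median(depth, median_bin)
    n = len(contigs)
    ncols = min(5, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 1.8 * nrows), squeeze=False, sharey=True
    )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for ax, contig in zip(axes.flat, contigs):
        x_mean = (np.arange(means[contig].size) + 0.5) * mean_bin
        ax.plot(x_mean, (means[contig] - median_depth) / median_depth,
                color="#1f77b4", lw=0.3, rasterized=True)
        x_med = (np.arange(medians[contig].size) + 0.5) * median_bin
        ax.plot(x_med, (medians[contig] - median_depth) / median_depth,
                color="#d62728", lw=1.2)
        for level in (-0.5, 0.0, 0.5):
            ax.axhline(level, color="0.6", lw=0.5, ls="--")
        for r in regions:
            if r.contig == contig:
                ax.axvspan(r.start, r.end, color=CLS_COLOR[r.cls], alpha=0.15)
        ax.set_ylim(-1, 1)
        ax.set_title(contig, fontsize=7)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def region_map_plot(
    regions_by_strain: dict[str, RegionSet],
    contigs: list[tuple[str, int]],
    genes: pd.DataFrame | None = None,
    path: str | Path | None = None,
) -> plt.Figure:
    """Genome-wide map of called regions, strains in rows.

    Contigs are concatenated longest to shortest along x; triploid
    regions are red blocks, haploid regions blue; gene positions, when
    given, are drawn as crosses on a bottom track.
    """
    if not regions_by_strain:
        raise ValueError("need at least one strain")
    ordered = sorted(contigs, key=lambda c: c[1], reverse=True)
    offsets: dict[str, int] = {}
    cursor = 0
    for name, length in ordered:
        offsets[name] = cursor
        cursor += length
    strains = list(regions_by_strain)
    n_rows = len(strains) + (1 if genes is not None else 0)
    fig, ax = plt.subplots(figsize=(10, 0.6 * n_rows + 1.2))
    for i, strain in enumerate(strains):
        y = len(strains) - i
        for r in regions_by_strain[strain]:
            if r.contig in offsets:
                x0 = offsets[r.contig] + r.start - 1
                ax.add_patch(
                    plt.Rectangle((x0, y - 0.3), r.span, 0.6, color=CLS_COLOR[r.cls], lw=0)
                )
    if genes is not None:
        xs = [
            offsets[row.contig] + (row.start + row.end) / 2
            for row in genes.itertuples(index=False)
            if row.contig in offsets
        ]
        ax.plot(xs, np.zeros(len(xs)), "x", color="0.3", ms=3)
    for name, _length in ordered:
        ax.axvline(offsets[name], color="0.8", lw=0.5)
    ax.set_xlim(0, cursor)
    ax.set_ylim(-0.6, len(strains) + 0.6)
    ax.set_yticks(
        ([0] if genes is not None else []) + list(range(1, len(strains) + 1)),
        (["genes"] if genes is not None else []) + list(reversed(strains)),
    )
    ax.set_xlabel("concatenated contigs (bp, longest to shortest)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
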