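"""The simulator must reproduce the statistical structure the caller
assumes: depth scaling with copy number, allele fractions tracking the
copy state, and bit-identical outputs for a fixed seed."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covploid import (
    CnSegment,
    NoiseSpec,
    make_reference,
    make_strain,
    simulate_allele_counts,
    simulate_depth,
)
from conftest import bare_reference


class TestMakeReference:
    def test_gene_count_follows_density(self):
        ref = make_reference(n_contigs=1, total_length=1_000_000, gene_density=300, seed=0)
        assert len(ref.genes) == 300
        assert (ref.genes["start"] >= 1).all()
        contig, length = ref.contigs[0]
        assert (ref.genes["end"] <= length).all()

    def test_genes_non_overlapping_within_contig(self):
        ref = make_reference(n_contigs=3, total_length=2_000_000, seed=1)
        for _, sub in ref.genes.groupby("contig"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()

    def test_same_seed_identical_models(self):
        a = make_reference(n_contigs=4, total_length=1_000_000, seed=7)
        b = make_reference(n_contigs=4, total_length=1_000_000, seed=7)
        assert a.contigs == b.contigs
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.het_loci, b.het_loci)
        assert a.categories == b.categories

    def test_het_locus_count_matches_binomial_sampling(self):
        # binomial oracle: N loci ~ Binomial(24 Mbp, 0.05) -> 1.2e6 +- 2%
        ref = make_reference(
            n_contigs=10, total_length=24_000_000, gene_density=1, het_density=0.05, seed=2
        )
        assert len(ref.het_loci) == pytest.approx(1.2e6, rel=0.02)

    @pytest.mark.parametrize("bad", [
        dict(n_contigs=0), dict(total_length=-5), dict(gene_density=0), dict(n_categories=0),
    ])
    def test_non_positive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            make_reference(**{**dict(n_contigs=2, total_length=100_000), **bad})


class TestMakeStrain:
    def test_copy_number_defaults_to_two(self):
        ref = bare_reference([("c1", 500_000)])
        strain = make_strain(ref, [], seed=0)
        assert strain.copy_number("c1", 250_000) == 2

    def test_segment_copy_number_lookup(self):
        ref = bare_reference([("c1", 500_000)])
        strain = make_strain(ref, [("c1", 100_001, 300_000, 3)], seed=0)
        assert strain.copy_number("c1", 200_000) == 3
        assert strain.copy_number("c1", 50_000) == 2

    def test_dropouts_short_and_outside_segments(self):
        ref = bare_reference([("c1", 1_000_000)])
        seg = CnSegment("c1", 400_001, 600_000, 3)
        strain = make_strain(ref, [seg], n_dropouts=10, seed=3)
        assert len(strain.dropout_artifacts) == 10
        for contig, start, end in strain.dropout_artifacts:
            assert end - start + 1 < 1000
            assert end < seg.start or start > seg.end

    def test_overlapping_segments_rejected(self):
        ref = bare_reference([("c1", 1_000_000)])
        with pytest.raises(ValueError, match="overlap"):
            make_strain(ref, [("c1", 1, 200_000, 3), ("c1", 150_000, 300_000, 1)], seed=0)

    def test_segment_outside_contig_rejected(self):
        ref = bare_reference([("c1", 100_000)])
        with pytest.raises(ValueError):
            make_strain(ref, [("c1", 50_000, 200_000, 3)], seed=0)


@pytest.fixture(scope="module")
def strain():
    ref = bare_reference([("c1", 1_000_000)])
    return make_strain(
        ref, [("c1", 100_001, 300_000, 3), ("c1", 600_001, 800_000, 1)], seed=0
    )


@pytest.fixture(scope="module")
def het_strain():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(1_000_000, size=30_000, replace=False)) + 1
    ref = bare_reference([("c1", 1_000_000)])
    ref.het_loci = pd.DataFrame({"contig": "c1", "pos": pos})
    return make_strain(
        ref, [("c1", 100_001, 300_000, 3), ("c1", 600_001, 800_000, 1)], seed=0
    )


@pytest.fixture(scope="module")
def loci(het_strain):
    return simulate_allele_counts(het_strain, depth_at_locus=100, seed=7)


class TestSimulateDepth:
    def test_segment_means_scale_with_copy_number(self, strain):
        depth = simulate_depth(strain, NoiseSpec(base_depth=100, seed=5))
        arr = depth.depths["c1"]
        assert arr[300_000:600_000].mean() == pytest.approx(100, rel=0.01)
        assert arr[100_000:300_000].mean() == pytest.approx(150, rel=0.02)
        assert arr[600_000:800_000].mean() == pytest.approx(50, rel=0.02)

    def test_seed_reproducibility(self, strain):
        a = simulate_depth(strain, NoiseSpec(100, seed=9))
        b = simulate_depth(strain, NoiseSpec(100, seed=9))
        assert np.array_equal(a.depths["c1"], b.depths["c1"])

    def test_negative_binomial_is_overdispersed(self, strain):
        nb = simulate_depth(strain, NoiseSpec(100, "negative_binomial", dispersion=5, seed=6))
        diploid = nb.depths["c1"][300_000:600_000]
        # variance = mu + mu^2/size = 100 + 2000
        assert diploid.var() == pytest.approx(2100, rel=0.1)

    def test_dropout_halves_depth(self):
        ref = bare_reference([("c1", 200_000)])
        strain = make_strain(ref, [], n_dropouts=20, seed=1)
        depth = simulate_depth(strain, NoiseSpec(100, seed=2))
        vals = np.concatenate(
            [depth.depths[c][s - 1 : e] for c, s, e in strain.dropout_artifacts]
        )
        assert vals.mean() == pytest.approx(50, rel=0.1)

    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(base_depth=0)
        with pytest.raises(ValueError):
            NoiseSpec(100, "negative_binomial")  # missing dispersion
        with pytest.raises(ValueError):
            NoiseSpec(100, "gaussian")


class TestSimulateAlleleCounts:
    @staticmethod
    def _fractions(frame):
        return frame["count_a"] / (frame["count_a"] + frame["count_b"])

    def test_diploid_loci_mean_fraction_half(self, loci):
        f = loci.frame
        diploid = f[(f["pos"] > 300_000) & (f["pos"] <= 600_000)]
        assert self._fractions(diploid).mean() == pytest.approx(0.5, abs=0.01)

    def test_triploid_loci_two_thirds_signal(self, loci):
        f = loci.frame
        tri = f[(f["pos"] > 100_000) & (f["pos"] <= 300_000)]
        mean_frac = self._fractions(tri).mean()
        # whichever haplotype was duplicated, the signal is coherent 2:1
        assert min(abs(mean_frac - 2 / 3), abs(mean_frac - 1 / 3)) < 0.02

    def test_haploid_loci_monoallelic(self, loci):
        f = loci.frame
        hap = f[(f["pos"] > 600_000) & (f["pos"] <= 800_000)]
        assert ((hap["count_a"] == 0) | (hap["count_b"] == 0)).all()

    def test_diploid_fraction_symmetric_about_half(self, loci):
        # two-sided sign test on allele-A fraction vs 0.5
        f = loci.frame
        diploid = f[(f["pos"] > 300_000) & (f["pos"] <= 600_000)]
        frac = self._fractions(diploid)
        above = int((frac > 0.5).sum())
        below = int((frac < 0.5).sum())
        p = stats.binomtest(above, above + below, 0.5).pvalue
        assert p > 0.01

    def test_triploid_depth_scales_at_loci(self, loci):
        f = loci.frame
        total = f["count_a"] + f["count_b"]
        tri = total[(f["pos"] > 100_000) & (f["pos"] <= 300_000)]
        assert tri.mean() == pytest.approx(150, rel=0.02)

    def test_seed_reproducibility(self, het_strain):
        a = simulate_allele_counts(het_strain, 50, seed=3)
        b = simulate_allele_counts(het_strain, 50, seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_non_positive_depth_rejected(self, het_strain):
        with pytest.raises(ValueError):
            simulate_allele_counts(het_strain, 0, seed=0)
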