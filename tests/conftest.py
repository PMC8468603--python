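import numpy as np
import pandas as pd
import pytest

from covploid import (
    CnSegment,
    NoiseSpec,
    ReferenceModel,
    make_reference,
    make_strain,
    simulate_depth,
)


def bare_reference(contigs):
    """A ReferenceModel with no genes, categories or het loci — handy when
    a test only needs depth."""
    return ReferenceModel(
        contigs=list(contigs),
        genes=pd.DataFrame(columns=["gene_id", "contig", "start", "end"]),
        categories={},
        het_loci=pd.DataFrame({"contig": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)}),
    )


@pytest.fixture(scope="session")
def small_ref():
    """Two-contig reference (~2.5 Mbp) with genes, categories, het loci."""
    return make_reference(n_contigs=2, total_length=2_500_000, het_density=0.002, seed=11)


@pytest.fixture(scope="session")
def aneuploid_strain(small_ref):
    """One 200 kbp triploid and one 200 kbp haploid segment on the larger
    contig, plus a handful of dropout artifacts."""
    contig, _ = small_ref.contigs[0]
    segments = [
        CnSegment(contig, 500_001, 700_000, 3),
        CnSegment(contig, 1_200_001, 1_400_000, 1),
    ]
    return make_strain(small_ref, segments, n_dropouts=5, seed=12)


@pytest.fixture(scope="session")
def aneuploid_depth(aneuploid_strain):
    return simulate_depth(aneuploid_strain, NoiseSpec(base_depth=100, seed=13))
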