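import pytest

import exintron as ex


@pytest.fixture(scope="session")
def small_cfg():
    return ex.SimulationConfig(seed=7, n_genes=8, n_lncrna=3, n_reads=20_000,
                               premrna_fraction=0.3)


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return ex.build_toy_reference(small_cfg)


@pytest.fixture(scope="session")
def small_index(small_ref):
    return ex.AnnotationIndex(small_ref.annotation, small_ref.sizes)


@pytest.fixture()
def two_gene_annotation():
    """Hand-built two-gene annotation on a 10 kb chromosome.

    A(+): exons (1000,1200) and (2000,2300); B(-): exon (1500,1600) sits
    inside A's intron, plus exon (4000,4200).
    """
    a = ex.GeneModel("A", "protein_coding", "chr1", "+",
                     [(1000, 1200), (2000, 2300)], {"A.t1": [(1000, 1200), (2000, 2300)]})
    b = ex.GeneModel("B", "protein_coding", "chr1", "-",
                     [(1500, 1600), (4000, 4200)], {"B.t1": [(1500, 1600), (4000, 4200)]})
    return ex.GenomeAnnotation([a, b]), {"chr1": 10_000}
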