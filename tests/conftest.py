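import pytest

from smalldisco import fixtures as fx


@pytest.fixture(scope="session")
def basic_fixture(tmp_path_factory):
    """One-chrom fixture: 4 planted antisense clusters over 6 genes, 10% noise."""
    outdir = tmp_path_factory.mktemp("basic_fx")
    clusters = [fx.ClusterSpec(gene_index=i, n_reads=12) for i in range(4)]
    return fx.make_fixture(outdir, seed=11, n_genes=6, clusters=clusters, noise_rate=0.1)


@pytest.fixture(scope="session")
def tailed_fixture(tmp_path_factory):
    """Fixture with planted 3' tails and no noise, for tail-mode tests."""
    outdir = tmp_path_factory.mktemp("tailed_fx")
    clusters = [fx.ClusterSpec(gene_index=i, n_reads=15) for i in range(3)]
    return fx.make_fixture(
        outdir, seed=23, n_genes=4, clusters=clusters,
        tail_spec={"": 0.5, "T": 0.2, "A": 0.15, "TT": 0.15}, noise_rate=0.0,
    )


@pytest.fixture(scope="session")
def junction_fixture(tmp_path_factory):
    """Two-exon gene with clusters at both exon edges plus spliced reads."""
    outdir = tmp_path_factory.mktemp("junction_fx")
    clusters = [fx.ClusterSpec(gene_index=0, junction=True, n_reads=10, junction_reads=3)]
    return fx.make_fixture(
        outdir, seed=31, n_genes=2, exons_per_gene=2, clusters=clusters, noise_rate=0.0,
    )
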