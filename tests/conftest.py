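import pytest

from mutlog import SimulationConfig, generate_genome, simulate_study, write_fixture


@pytest.fixture(scope="session")
def study_config():
    return SimulationConfig(seed=5)


@pytest.fixture(scope="session")
def study(study_config):
    """One full synthetic study, shared across the suite (read-only)."""
    return simulate_study(study_config)


@pytest.fixture(scope="session")
def assets(study):
    return study.assets


@pytest.fixture(scope="session")
def fixture_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    manifest = write_fixture(study, str(out))
    return out, manifest


@pytest.fixture(scope="session")
def toy_assets():
    """Tiny hand-checkable genome with one two-exon gene."""
    from mutlog import GeneModel, GenomeAssets, Interval

    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp
    gene = GeneModel(
        "geneA", "chr1", 5, 30, exons=((5, 10), (20, 25)), strand="+"
    )
    a = GenomeAssets(
        contigs={"chr1": seq},
        target_intervals=[Interval("chr1", 3, 32, "t1")],
        genes=[gene],
    )
    a.validate()
    return a
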