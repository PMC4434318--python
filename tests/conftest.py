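import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Miniature but complete simulation shared across tests."""
    from tssqc.synthetic_data import SimConfig, simulate

    cfg = SimConfig(seed=11, n_chromosomes=2, chrom_length=70_000, n_orfs=40,
                    n_cuts=10, n_xuts=10, n_suts=10, n_ncrna=5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    from tssqc.synthetic_data import write_fixtures

    d = tmp_path_factory.mktemp("smallsim")
    write_fixtures(small_sim, d, include_fastq=True)
    return d


@pytest.fixture(scope="session")
def small_pipeline(small_fixture_dir):
    from tssqc.cli_io import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(data_dir=str(small_fixture_dir)))


@pytest.fixture(scope="session")
def full_sim():
    """Default-configuration dataset (the acceptance-scale study)."""
    from tssqc.synthetic_data import SimConfig, simulate

    return simulate(SimConfig(seed=2))


@pytest.fixture(scope="session")
def full_pipeline(full_sim, tmp_path_factory):
    from tssqc.cli_io import PipelineConfig, run_pipeline
    from tssqc.synthetic_data import write_fixtures

    d = tmp_path_factory.mktemp("fullsim")
    write_fixtures(full_sim, d, include_fastq=False)
    return run_pipeline(PipelineConfig(data_dir=str(d)))


@pytest.fixture(scope="session")
def full_tap_tracks(full_pipeline):
    return [full_pipeline.tracks[s] for s in full_pipeline.size_factors.index]
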