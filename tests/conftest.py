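import pytest

from polymirts import (
    EnergyParams,
    PipelineConfig,
    ScoringParams,
    SyntheticConfig,
    generate,
    run_pipeline,
)


@pytest.fixture(scope="session")
def sparams():
    return ScoringParams()


@pytest.fixture(scope="session")
def eparams():
    return EnergyParams.default()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic scenario: 1 planted allele-specific site, 50 decoys."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(ds.mirnas, ds.transcripts, ds.genome, ds.snps, PipelineConfig())


@pytest.fixture(scope="session")
def small_config():
    """Reduced decoy population for the slower per-scenario pipeline tests."""
    return dict(n_decoy_mirnas=10)
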