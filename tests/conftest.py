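import pytest

from seedmet import PipelineConfig, SynthConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete synthetic experiment."""
    return SynthConfig(
        n_ils=10, n_plots=4, n_metabolites=16, set_sizes=(10, 6),
        n_blocks=2, rng_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at default study conditions, shared read-only."""
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(seed=1)
    artifacts = run_pipeline(config, outdir)
    return config, artifacts
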