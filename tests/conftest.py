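import pytest

from microsplice.simulate import GeneratorConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort: fast enough for unit tests, structure intact."""
    return GeneratorConfig(
        seed=11,
        n_tissues=3,
        n_tumor_per_tissue=25,
        n_normal_per_tissue=22,
        n_sfs=30,
        n_exons=80,
        n_targets=30,
        n_background_genes=60,
        n_signature_genes=20,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_null_bundle(small_config):
    return generate_cohorts(small_config.null())
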