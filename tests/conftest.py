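import pytest

from popdose import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """Moderate-size bundle under the default survey conditions."""
    return generate(GeneratorConfig(seed=11, population_size=300_000))


@pytest.fixture(scope="session")
def ct_only_config():
    """CT-only landscape, fully covered, for marginal-recovery checks."""
    return GeneratorConfig(
        seed=3,
        population_size=500_000,
        coverage_fraction=1.0,
        modality_frequencies={"CT": 135.0},
    )


@pytest.fixture(scope="session")
def ct_only_bundle(ct_only_config):
    return generate(ct_only_config)
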