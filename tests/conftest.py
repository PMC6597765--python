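import pytest

from coemerge import WithinHostParams, simulate_infection


@pytest.fixture(scope="session")
def wild_type_run():
    """Wild-type-only infection at default parameters."""
    return simulate_infection(WithinHostParams())


@pytest.fixture(scope="session")
def neutral_coinfection_run():
    """Neutral co-infection: identical strains, equal inocula summing to one."""
    return simulate_infection(WithinHostParams(w0=0.5, m0=0.5))


@pytest.fixture(scope="session")
def mutant_only_run():
    """Mutant-only infection at default parameters."""
    return simulate_infection(WithinHostParams(w0=0.0, m0=1.0))
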