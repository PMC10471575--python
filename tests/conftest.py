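import pytest

from depscreen import default_blueprint, generate, get_protocol, tabulate

#: Seed for the session cohort; any seed yields the same category counts
#: (cell sizes are blueprint-determined), only item values and order vary.
SESSION_SEED = 1234


@pytest.fixture(scope="session")
def blueprint():
    return default_blueprint()


@pytest.fixture(scope="session")
def cohort(blueprint):
    """The calibrated synthetic cohort (N = 12,668)."""
    return generate(blueprint, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def tables(cohort):
    """CohortTables for all three protocols over the session cohort."""
    return {name: tabulate(cohort, get_protocol(name)) for name in ("P1", "P2", "P3")}
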