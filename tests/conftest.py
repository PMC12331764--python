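import pytest

from phrasealign import align, fixture_worked_example, random_fixture


@pytest.fixture(scope="session")
def worked_example():
    """(tree, tier, expected table) of the eleven-word worked example."""
    return fixture_worked_example()


@pytest.fixture(scope="session")
def worked_table(worked_example):
    """Alignment table computed (not packaged) for the worked example."""
    tree, tier, _ = worked_example
    return align(tree, tier)


@pytest.fixture(scope="session")
def seeded_fixtures():
    """100 seeded synthetic (tree, tier) pairs for the property suites."""
    return [random_fixture(seed) for seed in range(100)]
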