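import pytest

from phylofoot import presets, simulate

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def promoter_cohort():
    return simulate.make_promoter_cohort(presets.promoter_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def utr_cohort():
    return simulate.make_utr_cohort(presets.utr_conservation_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def compensatory_cohort():
    return simulate.make_utr_cohort(presets.utr_compensatory_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def insertion_cohort():
    return simulate.make_utr_cohort(presets.primate_insertion_spec(FIXTURE_SEED))
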