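import pytest

from crcside import assign_side, cross_tabulate, reconstruct_fixture

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_dataset():
    return reconstruct_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_assigned(fixture_dataset):
    return {tl.patient_id: assign_side(tl) for tl in fixture_dataset.patients}


@pytest.fixture(scope="session")
def fixture_crosstab(fixture_dataset, fixture_assigned):
    return cross_tabulate(fixture_assigned, fixture_dataset.abstraction)
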