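import numpy as np
import pytest
from hypothesis import settings

from amplipair import (
    EvolutionParams,
    RegionMap,
    build_template,
    evolve_reference,
    train,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

REFERENCE_SEED = 7


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def reference(template):
    """Default synthetic reference: 2 phyla x 5 genera x 3 species x 3 strains."""
    return evolve_reference(template, EvolutionParams(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def db(reference):
    return reference.db


@pytest.fixture(scope="session")
def region_map(reference):
    return RegionMap.from_reference(reference)


@pytest.fixture(scope="session")
def species_model(db):
    """Word model trained on the full synthetic reference at species rank."""
    return train(db, rank="species")


@pytest.fixture(scope="session")
def heldout_split(db):
    """(training db, held-out record ids): strains T1/T2 train, T3 is held out."""
    train_ids = [r.id for r in db if not r.id.endswith("_T3")]
    test_ids = [r.id for r in db if r.id.endswith("_T3")]
    return db.subset(train_ids), test_ids


@pytest.fixture(scope="session")
def heldout_model(heldout_split):
    train_db, _ = heldout_split
    return train(train_db, rank="species")
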