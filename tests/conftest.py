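"""Shared fixtures: synthetic catalog, corpus, and a pretrained model.

Everything is generated programmatically from seeded specs, so the suite
needs no data files. The pretrained model is session-scoped because GRU
pretraining is the most expensive setup step and every consumer treats it
as read-only (biasing always copies).
"""

import pytest

from delgem import catalog, chem, fixtures, genlm

# Study conditions for the shared small fixture: a 600-member catalog with
# 40 actives planted in the 0.35-0.6 similarity band around the reference.
SMALL_SPEC = fixtures.FixtureSpec(
    seed=101,
    catalog_size=600,
    n_planted=40,
    del_library_size=800,
    del_replicates=2,
    del_enrichment_factor=10.0,
)

CORPUS_SIZE = 5000
CORPUS_SEED = 17
PRETRAIN_EPOCHS = 8
PRETRAIN_SEED = 23


@pytest.fixture(scope="session")
def small_catalog():
    """(records, truth) for the shared planted-actives catalog."""
    return fixtures.make_catalog(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_index(small_catalog):
    records, _truth = small_catalog
    return catalog.build_index(records)


@pytest.fixture(scope="session")
def reference():
    return chem.canonicalize(fixtures.REFERENCE_SMILES)


@pytest.fixture(scope="session")
def corpus():
    """Drug-like pretraining corpus from the fragment grammar."""
    return fixtures.make_corpus(CORPUS_SIZE, CORPUS_SEED)


@pytest.fixture(scope="session")
def pretrained(corpus):
    """A pretrained SMILES GRU shared read-only across the suite."""
    return genlm.pretrain(corpus, epochs=PRETRAIN_EPOCHS, seed=PRETRAIN_SEED)
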