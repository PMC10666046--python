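"""Shared fixtures.

Heavy artifacts (the default interaction world, its embedding tables and the
trained DPI model) are session-scoped: several tests probe different
properties of the same study condition, and retraining per test would
dominate the suite's runtime without adding coverage.
"""

import warnings

import numpy as np
import pytest

from oncodisco.dpi import assemble_dpi_dataset, train_dpi_model
from oncodisco.embeddings import (
    compound_corpus,
    protein_corpus,
    train_token_embedding,
)
from oncodisco.synthetic_data import default_interaction_world


@pytest.fixture(scope="session")
def world23():
    """Default interaction world at seed 23."""
    return default_interaction_world(23)


@pytest.fixture(scope="session")
def world23_tables(world23):
    """Protein and compound embedding tables trained on the world's corpora."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ptable = train_token_embedding(
            protein_corpus(world23.proteins), d=100, seed=1,
            kind="aa_3mer", k_or_radius=3,
        )
        ctable = train_token_embedding(
            compound_corpus(world23.compounds), d=100, seed=2,
            kind="substructure_id", k_or_radius=1,
        )
    return ptable, ctable


@pytest.fixture(scope="session")
def dpi_trained(world23, world23_tables):
    """Assembled dataset + cross-validated DPI model on the default world."""
    ptable, ctable = world23_tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = assemble_dpi_dataset(
            world23.positive_pairs,
            world23.score_table,
            world23.proteins,
            world23.compounds,
            ptable,
            ctable,
        )
        model, report = train_dpi_model(dataset, seed=23)
    return dataset, model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
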