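"""Shared fixtures: one synthetic reference set + trained bank per session.

Heavy objects (the 308-domain reference set, the HMM model bank, the
planted-genome suite) are built once and shared; tests must not mutate
them.
"""

import pytest

from t2pks.chemotype import load_rule_table
from t2pks.classifiers import ModelBank
from t2pks.synthetic import make_reference_set, standard_planted_suite

SESSION_SEED = 1


@pytest.fixture(scope="session")
def refset():
    return make_reference_set(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def rule_table():
    return load_rule_table()


@pytest.fixture(scope="session")
def bank(refset):
    """HMM + homology bank (no SVMs: the default best_cv policy calls HMMs)."""
    return ModelBank.train(refset.domains, seed=SESSION_SEED, with_svm=False)


@pytest.fixture(scope="session")
def planted_suite(refset, rule_table):
    return standard_planted_suite(refset, rule_table, seed=SESSION_SEED + 6)
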