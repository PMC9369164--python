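import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aidmap as am

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_terms(ids):
    return [am.DiseaseTerm(i, i) for i in ids]


@pytest.fixture
def hand_corpus():
    """Five documents over five diseases, built by hand so every count can
    be checked against mental set arithmetic.

    d0 in docs {0,1,2}; d1 in docs {2,3}; d2 in doc {4}; d3, d4 never.
    """
    spec = am.SyntheticCorpusSpec(n_diseases=5, n_blocks=1, n_documents=5, seed=0)
    docs = [
        frozenset({"d0"}),
        frozenset({"d0"}),
        frozenset({"d0", "d1"}),
        frozenset({"d1"}),
        frozenset({"d2"}),
    ]
    return am.SyntheticCorpus(documents=docs, truth=spec.blocks(), spec=spec)


@pytest.fixture
def small_corpus():
    """A modest random corpus with clear 3-block structure."""
    spec = am.SyntheticCorpusSpec(
        n_diseases=12, n_blocks=3, n_documents=3000, seed=42
    )
    return am.generate_corpus(spec)


@pytest.fixture
def small_matrix(small_corpus):
    backend = am.corpus_backend(small_corpus)
    terms = make_terms(small_corpus.disease_ids)
    matrix, result = am.matrix_from_backend(terms, backend)
    return matrix, result


def brute_force_counts(corpus, a, b):
    """Oracle: the four counts by per-document Python-set scanning."""
    docs_a = {i for i, d in enumerate(corpus.documents) if a in d}
    docs_b = {i for i, d in enumerate(corpus.documents) if b in d}
    return len(docs_a), len(docs_b), len(docs_a & docs_b), len(docs_a | docs_b)


def brute_force_association(corpus, a, b):
    _, _, n_and, n_or = brute_force_counts(corpus, a, b)
    return n_and / n_or if n_or else 0.0
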