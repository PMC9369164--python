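"""The block-topic corpus generator and its backend/reference adapters."""

import numpy as np
import pytest
from scipy import stats

import aidmap as am
from aidmap.counts import QueryParseError

from conftest import brute_force_counts, make_terms


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_diseases=3, n_blocks=5),
            dict(n_diseases=0),
            dict(within_block_boost=2.0, between_block_boost=3.0),
            dict(block_topic_prob=1.5),
            dict(n_diseases=3, base_mention_prob=np.array([0.1, 0.2])),
            dict(n_diseases=2, base_mention_prob=np.array([0.1, 1.2])),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            am.SyntheticCorpusSpec(**kwargs)

    def test_spec_json_round_trip(self, tmp_path):
        spec = am.SyntheticCorpusSpec(
            n_diseases=4, n_blocks=2, n_documents=10,
            base_mention_prob=np.array([0.1, 0.2, 0.3, 0.4]),
            gender_skew=np.array([0.2, 0.8]), seed=9,
        )
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = am.SyntheticCorpusSpec.from_json(path)
        assert back.n_diseases == 4
        assert np.array_equal(back.base_mention_prob, spec.base_mention_prob)
        assert back.blocks() == spec.blocks()


class TestGeneration:
    def test_fixed_seed_reproduces_corpus_bit_for_bit(self):
        spec = am.SyntheticCorpusSpec(n_diseases=8, n_blocks=2, n_documents=500, seed=7)
        c1, c2 = am.generate_corpus(spec), am.generate_corpus(spec)
        assert c1.documents == c2.documents
        assert c1.truth == c2.truth

    def test_equal_boosts_match_independence_baseline(self):
        """With no block effect the Jaccard expectation is the closed-form
        independence value p_a p_b / (p_a + p_b - p_a p_b)."""
        p = np.array([0.1, 0.2])
        spec = am.SyntheticCorpusSpec(
            n_diseases=2, n_blocks=1, n_documents=50_000,
            base_mention_prob=p, within_block_boost=1.0, between_block_boost=1.0,
            seed=11,
        )
        corpus = am.generate_corpus(spec)
        n_a, n_b, n_and, n_or = brute_force_counts(corpus, "d0", "d1")
        j_expected = (p[0] * p[1]) / (p[0] + p[1] - p[0] * p[1])
        j_hat = n_and / n_or
        # binomial MC error on the intersection fraction within the union
        se = np.sqrt(j_expected * (1 - j_expected) / n_or)
        assert abs(j_hat - j_expected) <= 3 * se

    def test_saturating_boost_drives_association_to_one(self):
        spec = am.SyntheticCorpusSpec(
            n_diseases=2, n_blocks=1, n_documents=200,
            base_mention_prob=np.array([0.05, 0.05]),
            within_block_boost=1000.0, between_block_boost=1.0, seed=3,
        )
        with pytest.warns(UserWarning, match="clipped"):
            corpus = am.generate_corpus(spec)
        _, assoc = am.empirical_association_matrix(corpus)
        assert assoc[0, 1] == 1.0

    def test_within_block_pairs_exceed_between_block_pairs(self, small_corpus):
        _, assoc = am.empirical_association_matrix(small_corpus)
        labels = small_corpus.disease_ids
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                group = (
                    within
                    if small_corpus.truth[labels[i]] == small_corpus.truth[labels[j]]
                    else between
                )
                group.append(assoc[i, j])
        assert np.mean(within) > 3 * np.mean(between)

    def test_no_block_effect_under_equal_boosts(self):
        """Kruskal-Wallis finds no within/between difference when the
        planted boost is switched off."""
        spec = am.SyntheticCorpusSpec(
            n_diseases=20, n_blocks=4, n_documents=5000,
            within_block_boost=1.0, between_block_boost=1.0, seed=23,
        )
        corpus = am.generate_corpus(spec)
        _, assoc = am.empirical_association_matrix(corpus)
        labels = corpus.disease_ids
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                (within if corpus.truth[labels[i]] == corpus.truth[labels[j]] else between).append(
                    assoc[i, j]
                )
        assert stats.kruskal(within, between).pvalue > 0.01

    def test_gendered_metadata_follows_blocks(self, small_corpus):
        terms = small_corpus.terms()
        by_block = {}
        for t in terms:
            by_block.setdefault(t.system_label, []).append(t.gender_female_fraction)
        # within-block gender spread is small compared to the [0,1] scale
        assert all(np.std(v) < 0.2 for v in by_block.values())


class TestBackend:
    def test_counts_match_brute_force_scan(self, small_corpus):
        backend = am.corpus_backend(small_corpus)
        ids = small_corpus.disease_ids
        for a, b in [(ids[0], ids[1]), (ids[2], ids[7]), (ids[5], ids[11])]:
            ta, tb = make_terms([a, b])
            pc = am.fetch_pair_counts(ta, tb, backend)
            assert (pc.n_a, pc.n_b, pc.n_and, pc.n_or) == brute_force_counts(
                small_corpus, a, b
            )

    def test_inclusion_exclusion_identity(self, small_corpus):
        backend = am.corpus_backend(small_corpus)
        ids = small_corpus.disease_ids
        for a, b in zip(ids[:-1], ids[1:]):
            ta, tb = make_terms([a, b])
            q = lambda op: am.build_pair_query(ta, tb, op)
            assert backend.count(q("OR")) + backend.count(q("AND")) == backend.count(
                am.build_term_query(ta)
            ) + backend.count(am.build_term_query(tb))

    def test_phrase_resolution_through_term_synonyms(self, hand_corpus):
        terms = [am.DiseaseTerm("d0", "Sjögren's syndrome", ("d0",))]
        backend = am.corpus_backend(hand_corpus, terms=terms)
        assert backend.count(am.build_term_query(terms[0])) == 3

    def test_unknown_phrase_counts_zero(self, hand_corpus):
        backend = am.corpus_backend(hand_corpus)
        assert backend.count('("never studied disease"[tiab])') == 0

    def test_malformed_query_raises(self, hand_corpus):
        backend = am.corpus_backend(hand_corpus)
        with pytest.raises(QueryParseError):
            backend.count('"d0" NEAR "d1"')


class TestReference:
    def test_zero_noise_reference_equals_empirical(self, small_corpus):
        ref = am.reference_from_truth(small_corpus, noise_sd=0.0)
        _, emp = am.empirical_association_matrix(small_corpus)
        assert np.array_equal(ref.values, emp)

    def test_noise_preserves_symmetry_and_nonnegativity(self, small_corpus):
        ref = am.reference_from_truth(small_corpus, noise_sd=0.05, seed=1)
        assert np.array_equal(ref.values, ref.values.T)
        assert (ref.values >= 0).all()

    def test_negative_noise_sd_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            am.reference_from_truth(small_corpus, noise_sd=-0.1)


class TestSerialization:
    def test_corpus_round_trip(self, hand_corpus, tmp_path):
        from aidmap.synthetic import load_documents

        path = tmp_path / "corpus.tsv"
        am.save_corpus(hand_corpus, path)
        assert load_documents(path) == hand_corpus.documents

    def test_truth_table(self, hand_corpus, tmp_path):
        path = tmp_path / "truth.tsv"
        am.save_truth(hand_corpus, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "id\tblock"
        assert len(lines) == 1 + hand_corpus.spec.n_diseases
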