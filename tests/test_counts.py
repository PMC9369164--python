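"""Query construction, backends, caching and pair fetching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import aidmap as am
from aidmap.counts import (
    FIELDS_ALL,
    FetchError,
    InconsistentCountsError,
    InvalidTermError,
    QueryParseError,
    SelfPairError,
    parse_query,
)

from conftest import make_terms

lupus = am.DiseaseTerm("lupus", "lupus")
sjogren = am.DiseaseTerm("sjogren", "sjögren")


class TestQueryBuilders:
    def test_single_name_restricted_fields(self):
        assert am.build_term_query(lupus) == '("lupus"[tiab] OR "lupus"[ot])'

    def test_synonyms_are_or_ed_with_field_tags(self):
        celiac = am.DiseaseTerm("celiac", "celiac disease", ("coeliac disease",))
        assert am.build_term_query(celiac) == (
            '("celiac disease"[tiab] OR "celiac disease"[ot]'
            ' OR "coeliac disease"[tiab] OR "coeliac disease"[ot])'
        )

    def test_all_fields_setting_drops_tiab_ot_tags(self):
        assert am.build_term_query(lupus, fields=FIELDS_ALL) == '("lupus"[All Fields])'

    def test_diacritics_queried_in_both_forms(self):
        q = am.build_term_query(sjogren)
        assert '"sjögren"[tiab]' in q and '"sjogren"[tiab]' in q

    def test_pair_query_shape(self):
        q = am.build_pair_query(lupus, am.DiseaseTerm("sjogren", "sjogren"), "AND")
        assert q == (
            '(("lupus"[tiab] OR "lupus"[ot])) AND '
            '(("sjogren"[tiab] OR "sjogren"[ot]))'
        )

    def test_pair_query_commutative(self):
        assert am.build_pair_query(lupus, sjogren, "OR") == am.build_pair_query(
            sjogren, lupus, "OR"
        )

    def test_invalid_inputs_raise(self):
        with pytest.raises(InvalidTermError):
            am.DiseaseTerm("x", "")
        with pytest.raises(ValueError):
            am.build_pair_query(lupus, sjogren, op="XOR")
        with pytest.raises(SelfPairError):
            am.build_pair_query(lupus, lupus)
        with pytest.raises(ValueError):
            am.build_term_query(lupus, fields="full-text")

    @given(st.text(alphabet="abcdefghij", min_size=1), st.text(alphabet="klmnopqrst", min_size=1))
    def test_pair_key_is_order_invariant(self, a, b):
        assert am.pair_key(a, b) == am.pair_key(b, a)
        assert am.pair_key(a, b) == tuple(sorted([a, b]))


class TestQueryParser:
    def test_round_trips_builder_output(self):
        q = am.build_pair_query(lupus, sjogren, "AND")
        tree = parse_query(q)  # no error and fully consumed
        assert tree.op == "AND"

    @pytest.mark.parametrize(
        "bad",
        ['"unterminated', '"a"[tiab', 'lupus AND sjogren', '("a"[tiab]', '"a" NOT "b"'],
    )
    def test_unsupported_constructs_raise(self, bad):
        with pytest.raises(QueryParseError):
            parse_query(bad)


class _CountingBackend:
    """Wraps a backend and counts how many queries actually reach it."""

    def __init__(self, inner):
        self.inner = inner
        self.backend_id = inner.backend_id
        self.snapshot_consistent = inner.snapshot_consistent
        self.hits = 0

    def count(self, query):
        self.hits += 1
        return self.inner.count(query)


class TestFetching:
    def test_counts_match_set_arithmetic(self, hand_corpus):
        backend = am.corpus_backend(hand_corpus)
        a, b = make_terms(["d0", "d1"])
        pc = am.fetch_pair_counts(a, b, backend)
        assert (pc.n_a, pc.n_b, pc.n_and, pc.n_or) == (3, 2, 1, 4)

    def test_unmentioned_disease_counts_zero(self, hand_corpus):
        backend = am.corpus_backend(hand_corpus)
        assert am.fetch_term_count(am.DiseaseTerm("d3", "d3"), backend) == 0

    def test_snapshot_backend_enforces_inclusion_exclusion(self, hand_corpus):
        class Broken:
            backend_id = "broken"
            snapshot_consistent = True

            def count(self, query):
                return 5 if "AND" in query else 10

        a, b = make_terms(["a", "b"])
        with pytest.raises(InconsistentCountsError):
            am.fetch_pair_counts(a, b, Broken())

    def test_cache_prevents_repeat_backend_hits(self, hand_corpus, tmp_path):
        backend = _CountingBackend(am.corpus_backend(hand_corpus))
        cache = am.CountCache(tmp_path / "cache.tsv")
        a, b = make_terms(["d0", "d1"])
        pc1 = am.fetch_pair_counts(a, b, backend, cache)
        hits_after_first = backend.hits
        pc2 = am.fetch_pair_counts(a, b, backend, cache)
        assert pc1 == pc2
        assert backend.hits == hits_after_first

    def test_cache_key_is_pair_order_invariant(self, hand_corpus, tmp_path):
        backend = _CountingBackend(am.corpus_backend(hand_corpus))
        cache = am.CountCache(tmp_path / "cache.tsv")
        a, b = make_terms(["d0", "d1"])
        am.fetch_pair_counts(a, b, backend, cache)
        hits = backend.hits
        flipped = am.fetch_pair_counts(b, a, backend, cache)
        assert backend.hits == hits
        assert flipped.key == ("d0", "d1")

    def test_cache_survives_reload_from_disk(self, hand_corpus, tmp_path):
        backend = _CountingBackend(am.corpus_backend(hand_corpus))
        path = tmp_path / "cache.tsv"
        a, b = make_terms(["d0", "d1"])
        pc1 = am.fetch_pair_counts(a, b, backend, am.CountCache(path))
        reloaded = am.CountCache(path)
        hits = backend.hits
        pc2 = am.fetch_pair_counts(a, b, backend, reloaded)
        assert backend.hits == hits
        assert pc2.n_and == pc1.n_and

    def test_all_pairs_combinatorics_and_resume(self, small_corpus, tmp_path):
        backend = _CountingBackend(am.corpus_backend(small_corpus))
        cache = am.CountCache(tmp_path / "cache.tsv")
        terms = make_terms(small_corpus.disease_ids[:7])
        result = am.fetch_all_pairs(terms, backend, cache)
        assert len(result.pairs) == 21
        assert len(result.singletons) == 7
        hits = backend.hits
        am.fetch_all_pairs(terms, backend, cache)  # rerun: all cached
        assert backend.hits == hits

    def test_too_few_terms_rejected(self, hand_corpus):
        with pytest.raises(ValueError):
            am.fetch_all_pairs(make_terms(["d0"]), am.corpus_backend(hand_corpus))


class TestTableBackendAndTermIO:
    def test_table_backend_round_trip(self, tmp_path):
        q = am.build_term_query(lupus)
        path = tmp_path / "counts.tsv"
        path.write_text(f"query\tcount\n{q}\t123\n")
        backend = am.TableBackend(path)
        assert backend.count(q) == 123
        with pytest.raises(FetchError):
            backend.count("unknown")

    def test_term_table_round_trip(self, tmp_path):
        terms = [
            am.DiseaseTerm("sle", "systemic lupus erythematosus", ("lupus",),
                           gender_female_fraction=0.9, onset_age=30.0,
                           prevalence=1e-3, system_label="multiple"),
            am.DiseaseTerm("ms", "multiple sclerosis"),
        ]
        path = tmp_path / "terms.tsv"
        am.save_terms(terms, path)
        assert am.load_terms(path) == terms

    def test_training_fixture_has_seven_diseases(self):
        terms = am.training_terms()
        assert len(terms) == 7
        assert {t.id for t in terms} == {"sle", "sjogren", "t1d", "aitd", "ra", "ms", "ssc"}
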