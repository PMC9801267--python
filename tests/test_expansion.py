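"""Synonym weighting and topic-query assembly."""

import numpy as np
import pytest

from pmir.corpus import Article, Topic
from pmir.expansion import (
    RetrieverConfig,
    SynonymTable,
    build_topic_query,
    retrieve_candidates,
    synonym_weights,
)
from pmir.index import Bm25Params, DisMax, InvertedIndex, SynonymClause, TermClause, execute

from .oracles import naive_execute


def _corpus_with_dfs(term_a: str, n_a: int, term_b: str, n_b: int, n_total: int):
    """A corpus where term_a appears in n_a docs and term_b in n_b docs."""
    docs = []
    for i in range(n_total):
        extra = []
        if i < n_a:
            extra.append(term_a)
        if i < n_b:
            extra.append(term_b)
        docs.append(Article(id=f"D{i:04d}", title="filler text", abstract=" ".join(extra)))
    return docs


class TestSynonymWeights:
    def test_normalized_document_frequency(self):
        index = InvertedIndex(_corpus_with_dfs("neoplasm", 100, "tumour", 10, 110))
        weights = synonym_weights(["neoplasm", "tumour"], index)
        assert [w.weight for w in weights] == [1.0, 0.1]

    def test_single_synonym_self_normalizes(self):
        index = InvertedIndex(_corpus_with_dfs("cancer", 5, "x", 0, 10))
        (w,) = synonym_weights(["cancer"], index)
        assert w.weight == 1.0

    def test_all_absent_fall_back_to_one(self):
        index = InvertedIndex(_corpus_with_dfs("a", 3, "b", 1, 5))
        weights = synonym_weights(["zz1", "zz2"], index)
        assert [w.weight for w in weights] == [1.0, 1.0]

    def test_multiword_df_requires_all_tokens(self):
        docs = [
            Article(id="D1", title="breast cancer", abstract=""),
            Article(id="D2", title="breast surgery", abstract=""),
            Article(id="D3", title="cancer", abstract="breast"),
        ]
        index = InvertedIndex(docs)
        weights = synonym_weights(["breast cancer", "breast"], index)
        # "breast cancer" needs both tokens (D1, D3); "breast" alone is in all 3
        assert weights[0].weight == pytest.approx(2 / 3)
        assert weights[1].weight == 1.0


class TestSynonymTable:
    def test_original_term_always_first(self):
        table = SynonymTable({"melanoma": ["skin cancer", "melanoma"]})
        assert table.expand("melanoma")[0] == "melanoma"

    def test_unknown_term_expands_to_itself(self):
        assert SynonymTable().expand("nsclc") == ["nsclc"]

    def test_file_round_trip(self, tmp_path):
        table = SynonymTable({"braf": ["b raf", "braf1"], "melanoma": ["skin melanoma"]})
        path = tmp_path / "syn.tsv"
        table.write(path)
        back = SynonymTable.read(path)
        assert back.expand("braf") == table.expand("braf")
        assert back.expand("melanoma") == table.expand("melanoma")


class TestBuildTopicQuery:
    TOPIC = Topic(1, "colorectal cancer", "abl1", "regorafenib")

    def _index(self):
        return InvertedIndex(
            [
                Article(id="D1", title="colorectal cancer", abstract="regorafenib trial abl1"),
                Article(id="D2", title="bowel cancer", abstract="regorafenib patient"),
            ]
        )

    def test_empty_table_structure(self):
        q = build_topic_query(self.TOPIC, SynonymTable(), self._index())
        disease_dm, treatment_dm = q.must
        assert isinstance(disease_dm, DisMax) and len(disease_dm.clauses) == 2  # 1 syn x 2 fields
        assert len(treatment_dm.clauses) == 2
        gene_dm = q.should[0]
        assert isinstance(gene_dm, DisMax)
        keyword_clauses = [c for c in q.should[1:]]
        assert {(c.term, c.field) for c in keyword_clauses} == {
            ("trial", "title"),
            ("trial", "abstract"),
            ("patient", "title"),
            ("patient", "abstract"),
        }

    def test_two_disease_synonyms_give_four_subclauses(self):
        table = SynonymTable({"colorectal cancer": ["bowel cancer"]})
        q = build_topic_query(self.TOPIC, table, self._index())
        disease_dm = q.must[0]
        assert len(disease_dm.clauses) == 4
        assert all(isinstance(c, SynonymClause) for c in disease_dm.clauses)

    def test_no_keywords_leaves_only_gene_dismax(self):
        config = RetrieverConfig(keywords=())
        q = build_topic_query(self.TOPIC, SynonymTable(), self._index(), config)
        assert len(q.should) == 1

    def test_field_boosts_and_tie_breaker_propagate(self):
        config = RetrieverConfig(tie_breaker=0.5, title_boost=4.0)
        q = build_topic_query(self.TOPIC, SynonymTable(), self._index(), config)
        disease_dm = q.must[0]
        assert disease_dm.tie_breaker == 0.5
        title_clause = next(c for c in disease_dm.clauses if c.field == "title")
        assert title_clause.boost == pytest.approx(4.0)

    def test_treatment_is_never_expanded(self):
        table = SynonymTable({"regorafenib": ["stivarga"]})
        q = build_topic_query(self.TOPIC, table, self._index())
        treatment_dm = q.must[1]
        texts = {c.text for c in treatment_dm.clauses}
        assert texts == {"regorafenib"}


class TestRetrieveCandidates:
    def test_missing_treatment_term_gives_empty_result(self):
        index = InvertedIndex([Article(id="D1", title="colorectal cancer", abstract="abl1")])
        topic = Topic(1, "colorectal cancer", "abl1", "regorafenib")
        assert retrieve_candidates(topic, SynonymTable(), index) == []

    def test_synonym_only_document_needs_expansion(self):
        # synonym shares no tokens with the canonical term (bag-of-tokens
        # matching would otherwise pick up partial-word overlap)
        docs = [
            Article(id="D1", title="cutaneous neoplasm", abstract="regorafenib"),
            Article(id="D2", title="melanoma", abstract="regorafenib"),
        ]
        index = InvertedIndex(docs)
        topic = Topic(1, "melanoma", "abl1", "regorafenib")
        table = SynonymTable({"melanoma": ["cutaneous neoplasm"]})
        with_exp = {h.article_id for h in retrieve_candidates(topic, table, index)}
        without = {
            h.article_id
            for h in retrieve_candidates(
                topic, table, index, RetrieverConfig(query_expansion=False)
            )
        }
        assert "D1" in with_exp and "D2" in with_exp
        assert without == {"D2"}

    def test_cap_truncates_to_oracle_prefix(self):
        rng = np.random.default_rng(5)
        docs = [
            Article(
                id=f"D{i:02d}",
                title=" ".join(rng.choice(["melanoma", "braf", "x", "y"], size=3)),
                abstract="dabrafenib " + " ".join(rng.choice(["trial", "patient", "z"], size=3)),
            )
            for i in range(20)
        ]
        index = InvertedIndex(docs)
        topic = Topic(1, "melanoma", "braf", "dabrafenib")
        config = RetrieverConfig(candidate_cap=5)
        got = retrieve_candidates(topic, SynonymTable(), index, config)
        assert len(got) == 5
        query = build_topic_query(topic, SynonymTable(), index, config)
        expected = naive_execute(docs, query, Bm25Params(), limit=5)
        assert [h.article_id for h in got] == [a for a, _ in expected]


class TestAblationInvariants:
    def test_expansion_recall_dominates_at_every_cutoff(self, small_benchmark):
        bench = small_benchmark
        index = InvertedIndex(bench.articles)
        for topic in bench.topics:
            relevant = {
                a for a, t in bench.qrels.judged_articles(topic.id).items() if t >= 1
            }
            on = [h.article_id for h in retrieve_candidates(topic, bench.synonym_table, index)]
            off = [
                h.article_id
                for h in retrieve_candidates(
                    topic, bench.synonym_table, index, RetrieverConfig(query_expansion=False)
                )
            ]
            for k in (5, 10, 50, len(on) + len(off)):
                assert len(relevant & set(on[:k])) >= len(relevant & set(off[:k]))

    def test_keywords_never_change_match_set(self, small_benchmark):
        bench = small_benchmark
        index = InvertedIndex(bench.articles)
        for topic in bench.topics:
            with_kw = {h.article_id for h in retrieve_candidates(topic, bench.synonym_table, index)}
            no_kw = {
                h.article_id
                for h in retrieve_candidates(
                    topic, bench.synonym_table, index, RetrieverConfig(keywords=())
                )
            }
            assert with_kw == no_kw
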