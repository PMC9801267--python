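"""Fielded inverted index with Okapi BM25 scoring and engine-style queries.

Title and abstract are indexed as separate fields with separate length
normalization, mirroring a Lucene-style search engine. Queries are a small
algebra — term clauses, bag-of-tokens synonym clauses, ``dis_max`` combiners
and a boolean must/should wrapper — with the scoring semantics search engines
give them: a clause *matches* a document iff its score is positive, a boolean
query matches iff every must clause matches, and ``dis_max`` scores the best
sub-clause plus ``tie_breaker`` times the rest.

The BM25 variant uses the non-negative idf ``ln(1 + (N − df + 0.5)/(df + 0.5))``
so that even collection-wide terms contribute positive scores.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .corpus import Article

FIELDS = ("title", "abstract")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercased maximal alphanumeric runs, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Bm25Params:
    """Okapi BM25 parameters: saturation ``k1`` and length normalization ``b``."""

    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")


class InvertedIndex:
    """Per-field postings with document frequencies and length statistics."""

    def __init__(self, articles: Iterable[Article]) -> None:
        articles = list(articles)
        if not articles:
            raise ValueError("cannot build an index over an empty collection")
        self.n_docs = len(articles)
        self.article_ids: list[str] = [a.id for a in articles]
        # field -> term -> {doc id: tf}
        self._postings: dict[str, dict[str, dict[str, int]]] = {f: {} for f in FIELDS}
        self._doc_len: dict[str, dict[str, int]] = {f: {} for f in FIELDS}
        self._avg_len: dict[str, float] = {}
        # term -> doc ids containing it in any field (for synonym df counting)
        self._docs_with_term: dict[str, set[str]] = {}
        for a in articles:
            for fieldname in FIELDS:
                tokens = tokenize(getattr(a, fieldname))
                self._doc_len[fieldname][a.id] = len(tokens)
                field_postings = self._postings[fieldname]
                for tok in tokens:
                    field_postings.setdefault(tok, {})
                    field_postings[tok][a.id] = field_postings[tok].get(a.id, 0) + 1
                    self._docs_with_term.setdefault(tok, set()).add(a.id)
        for fieldname in FIELDS:
            lengths = self._doc_len[fieldname]
            self._avg_len[fieldname] = sum(lengths.values()) / len(lengths)

    # -- statistics ---------------------------------------------------------

    def df(self, term: str, fieldname: str) -> int:
        """Document frequency of a single token within one field."""
        return len(self._postings[fieldname].get(term, ()))

    def tf(self, term: str, fieldname: str, article_id: str) -> int:
        return self._postings[fieldname].get(term, {}).get(article_id, 0)

    def doc_length(self, fieldname: str, article_id: str) -> int:
        return self._doc_len[fieldname][article_id]

    def avg_length(self, fieldname: str) -> float:
        return self._avg_len[fieldname]

    def postings(self, term: str, fieldname: str) -> list[tuple[str, int]]:
        """Postings list (article id, tf) sorted by article id."""
        return sorted(self._postings[fieldname].get(term, {}).items())

    def docs_containing(self, term: str) -> frozenset[str]:
        """Ids of documents containing a token in title or abstract."""
        return frozenset(self._docs_with_term.get(term, ()))

    def document_frequency(self, text: str) -> int:
        """Collection-wide df of a (possibly multiword) expression.

        Counts documents containing *all* tokens of the expression in title
        or abstract. Empty expressions have df 0.
        """
        tokens = tokenize(text)
        if not tokens:
            return 0
        docsets = [self._docs_with_term.get(t, set()) for t in tokens]
        if any(not d for d in docsets):
            return 0
        result = set(docsets[0])
        for d in docsets[1:]:
            result &= d
        return len(result)


def bm25_score(
    index: InvertedIndex,
    term: str,
    fieldname: str,
    article_id: str,
    params: Bm25Params = Bm25Params(),
) -> float:
    """Okapi BM25 contribution of one token in one field; 0 if absent."""
    tf = index.tf(term, fieldname, article_id)
    if tf == 0:
        return 0.0
    n = index.n_docs
    df = index.df(term, fieldname)
    idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
    length = index.doc_length(fieldname, article_id)
    avg = index.avg_length(fieldname)
    return idf * tf * (params.k1 + 1.0) / (tf + params.k1 * (1.0 - params.b + params.b * length / avg))


# ---------------------------------------------------------------------------
# Query algebra


@dataclass(frozen=True)
class TermClause:
    """A single-token match in one field, scaled by a boost."""

    term: str
    field: str
    boost: float = 1.0

    def __post_init__(self) -> None:
        if self.boost < 0:
            raise ValueError("boost must be >= 0")


@dataclass(frozen=True)
class SynonymClause:
    """A bag-of-tokens match of one (possibly multiword) expression in one field.

    The boost bundles the synonym weight and the field boost. Matching is
    engine "match" semantics: any token present matches, and the score is the
    boosted sum of per-token BM25 scores (no phrase constraint).
    """

    text: str
    field: str
    boost: float = 1.0

    def __post_init__(self) -> None:
        if self.boost < 0:
            raise ValueError("boost must be >= 0")


@dataclass(frozen=True)
class DisMax:
    """Best-sub-clause score plus ``tie_breaker`` times the remaining scores."""

    clauses: tuple
    tie_breaker: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if not 0.0 <= self.tie_breaker <= 1.0:
            raise ValueError("tie_breaker must be in [0, 1]")


@dataclass(frozen=True)
class Bool:
    """Boolean query: all must clauses required, should clauses add score."""

    must: tuple = ()
    should: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "must", tuple(self.must))
        object.__setattr__(self, "should", tuple(self.should))


Query = Union[TermClause, SynonymClause, DisMax, Bool]


@dataclass(frozen=True)
class ScoredHit:
    """A matching article with its retrieval score (the ``es`` feature)."""

    article_id: str
    score: float


def score_query(
    index: InvertedIndex, query: Query, article_id: str, params: Bm25Params = Bm25Params()
) -> float | None:
    """Score one document against a query; ``None`` means "no hit".

    A clause matches iff its score is strictly positive; a boolean query is
    a hit only if every must clause matches, and non-matching should clauses
    contribute nothing.
    """
    if isinstance(query, TermClause):
        s = query.boost * bm25_score(index, query.term, query.field, article_id, params)
        return s if s > 0 else None
    if isinstance(query, SynonymClause):
        total = sum(bm25_score(index, t, query.field, article_id, params) for t in tokenize(query.text))
        s = query.boost * total
        return s if s > 0 else None
    if isinstance(query, DisMax):
        scores = [
            s for s in (score_query(index, c, article_id, params) for c in query.clauses) if s is not None
        ]
        if not scores:
            return None
        best = max(scores)
        return best + query.tie_breaker * (sum(scores) - best)
    if isinstance(query, Bool):
        total = 0.0
        for clause in query.must:
            s = score_query(index, clause, article_id, params)
            if s is None:
                return None
            total += s
        any_should = False
        for clause in query.should:
            s = score_query(index, clause, article_id, params)
            if s is not None:
                any_should = True
                total += s
        # with no must clauses, at least one should clause has to match
        if not query.must and not any_should:
            return None
        return total
    raise TypeError(f"not a query: {query!r}")


def _candidate_docs(index: InvertedIndex, query: Query) -> frozenset[str]:
    """Superset of documents a query can match, from postings only."""
    if isinstance(query, TermClause):
        return index.docs_containing(query.term) if query.boost > 0 else frozenset()
    if isinstance(query, SynonymClause):
        if query.boost <= 0:
            return frozenset()
        docs: set[str] = set()
        for tok in tokenize(query.text):
            docs |= index.docs_containing(tok)
        return frozenset(docs)
    if isinstance(query, DisMax):
        docs = set()
        for c in query.clauses:
            docs |= _candidate_docs(index, c)
        return frozenset(docs)
    if isinstance(query, Bool):
        if query.must:
            sets = [_candidate_docs(index, c) for c in query.must]
            result = set(sets[0])
            for s in sets[1:]:
                result &= s
            return frozenset(result)
        docs = set()
        for c in query.should:
            docs |= _candidate_docs(index, c)
        return frozenset(docs)
    raise TypeError(f"not a query: {query!r}")


def execute(
    index: InvertedIndex, query: Query, params: Bm25Params = Bm25Params(), limit: int = 10_000
) -> list[ScoredHit]:
    """All matching documents, best first; ties broken by ascending id.

    Candidate narrowing via postings is exact: a document outside the
    candidate superset cannot match, so results equal scoring every document.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    hits = []
    for article_id in _candidate_docs(index, query):
        s = score_query(index, query, article_id, params)
        if s is not None:
            hits.append(ScoredHit(article_id, s))
    hits.sort(key=lambda h: (-h.score, h.article_id))
    return hits[:limit]
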