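"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's index and metric code paths: document
statistics are recomputed by scanning article texts on every call, queries
are evaluated against every document, and DCG sums are assembled directly
from definitions.
"""

from __future__ import annotations

import math

from pmir.corpus import Article, JudgmentSet, RunRanking
from pmir.index import Bm25Params, Bool, DisMax, SynonymClause, TermClause


def naive_tokenize(text: str) -> list[str]:
    """Character-walk tokenizer (independent of the regex implementation)."""
    tokens, current = [], []
    for ch in text.lower():
        if ch.isascii() and (ch.isalpha() or ch.isdigit()):
            current.append(ch)
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return tokens


class NaiveCorpus:
    """Scans articles on demand; no postings, no caching."""

    def __init__(self, articles: list[Article]) -> None:
        self.articles = articles

    def tokens(self, article: Article, fieldname: str) -> list[str]:
        return naive_tokenize(getattr(article, fieldname))

    def df(self, term: str, fieldname: str) -> int:
        return sum(1 for a in self.articles if term in self.tokens(a, fieldname))

    def avg_len(self, fieldname: str) -> float:
        return sum(len(self.tokens(a, fieldname)) for a in self.articles) / len(self.articles)


def naive_bm25(corpus: NaiveCorpus, term: str, fieldname: str, article: Article, params: Bm25Params) -> float:
    tf = corpus.tokens(article, fieldname).count(term)
    if tf == 0:
        return 0.0
    n = len(corpus.articles)
    df = corpus.df(term, fieldname)
    idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
    length = len(corpus.tokens(article, fieldname))
    avg = corpus.avg_len(fieldname)
    denom = tf + params.k1 * (1.0 - params.b + params.b * length / avg)
    return idf * tf * (params.k1 + 1.0) / denom


def naive_score(corpus: NaiveCorpus, query, article: Article, params: Bm25Params):
    """Recursive scoring from definitions; None means no hit."""
    if isinstance(query, TermClause):
        s = query.boost * naive_bm25(corpus, query.term, query.field, article, params)
        return s if s > 0 else None
    if isinstance(query, SynonymClause):
        total = sum(
            naive_bm25(corpus, tok, query.field, article, params)
            for tok in naive_tokenize(query.text)
        )
        s = query.boost * total
        return s if s > 0 else None
    if isinstance(query, DisMax):
        scores = [naive_score(corpus, c, article, params) for c in query.clauses]
        scores = [s for s in scores if s is not None]
        if not scores:
            return None
        return max(scores) + query.tie_breaker * (sum(scores) - max(scores))
    if isinstance(query, Bool):
        total = 0.0
        for clause in query.must:
            s = naive_score(corpus, clause, article, params)
            if s is None:
                return None
            total += s
        any_should = False
        for clause in query.should:
            s = naive_score(corpus, clause, article, params)
            if s is not None:
                any_should = True
                total += s
        if not query.must and not any_should:
            return None
        return total
    raise TypeError(query)


def naive_execute(articles: list[Article], query, params: Bm25Params, limit: int):
    """Score every document; sort by descending score, ascending id; truncate."""
    corpus = NaiveCorpus(articles)
    hits = []
    for a in articles:
        s = naive_score(corpus, query, a, params)
        if s is not None:
            hits.append((a.id, s))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits[:limit]


def direct_ndcg(ranking: RunRanking, qrels: JudgmentSet, gains: dict[int, float], k: int) -> float:
    """Direct-sum NDCG from the definition, assembled independently."""
    judged = qrels.judged_articles(ranking.topic_id)
    dcg = sum(
        gains[judged[a]] / math.log2(r + 1)
        for a, r, _ in ranking.entries
        if r <= k and a in judged
    )
    ideal = sorted((gains[t] for t in judged.values()), reverse=True)[:k]
    idcg = sum(g / math.log2(i + 2) for i, g in enumerate(ideal))
    return dcg / idcg if idcg > 0 else 0.0


def random_article(rng, article_id: str, vocab: list[str], max_tokens: int = 8) -> Article:
    title = " ".join(rng.choice(vocab, size=rng.integers(0, max_tokens + 1)))
    abstract = " ".join(rng.choice(vocab, size=rng.integers(0, max_tokens + 1)))
    return Article(id=article_id, title=title, abstract=abstract)


def random_query(rng, vocab: list[str]):
    """Random boolean/dis_max query over a small vocabulary (plus misses)."""

    def leaf():
        field = str(rng.choice(["title", "abstract"]))
        boost = float(rng.choice([0.25, 1.0, 2.0, 3.0]))
        if rng.random() < 0.5:
            return TermClause(str(rng.choice(vocab + ["zzmiss"])), field, boost)
        n_words = int(rng.integers(1, 4))
        text = " ".join(rng.choice(vocab + ["zzmiss"], size=n_words))
        return SynonymClause(text, field, boost)

    def dismax():
        n = int(rng.integers(1, 4))
        return DisMax(tuple(leaf() for _ in range(n)), float(rng.choice([0.0, 0.5, 0.8, 1.0])))

    def clause():
        return dismax() if rng.random() < 0.6 else leaf()

    n_must = int(rng.integers(0, 3))
    n_should = int(rng.integers(0, 3))
    if n_must == 0 and n_should == 0:
        n_must = 1
    return Bool(
        must=tuple(clause() for _ in range(n_must)),
        should=tuple(clause() for _ in range(n_should)),
    )
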