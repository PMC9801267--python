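"""Synthetic benchmark generator: corpus, topics, synonyms, truth, expert.

The generator emulates the statistical structure the retrieval pipeline
assumes, without any linguistic realism:

* each topic is a (disease, gene, treatment) triple of unique synthetic
  terms, with disease and gene carrying a small synonym set;
* topic-bearing documents mention the treatment term, usually the disease
  (canonical or a synonym, at a controlled substitution rate), and often the
  gene, embedded in background vocabulary;
* publication types follow realistic MEDLINE frequencies and citation counts
  follow a discretized log-normal (heavy-tailed, like real citation data);
* a simulated expert assigns evidence tiers {0..4} as a monotone function of
  concept-match quality, publication-type score, and citation quantile —
  honoring the ordering of the manual publication-type ratings (a
  meta-analysis never scores below a comment, all else equal).

Everything is bit-reproducible per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import Article, JudgmentSet, Topic
from .expansion import SynonymTable
from .index import tokenize
from .rerank import CorpusStats, publication_type_score

#: MEDLINE-like publication-type frequencies for the synthetic corpus.
DEFAULT_PUB_TYPE_FREQS: dict[str, float] = {
    "journal article": 0.45,
    "review": 0.12,
    "clinical trial": 0.09,
    "case reports": 0.08,
    "observational study": 0.06,
    "letter": 0.04,
    "comment": 0.04,
    "editorial": 0.03,
    "english abstract": 0.03,
    "meta-analysis": 0.03,
    "systematic review": 0.02,
    "published erratum": 0.005,
    "retraction of publication": 0.005,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Benchmark shape and noise knobs.

    The defaults define the package's reference benchmark: 5,000 documents,
    10 topics with ~50 bearing documents each, 2 non-canonical synonyms per
    disease/gene concept, and a 0.3 synonym-substitution rate (a bearing
    document names the disease or gene by a non-canonical synonym with
    probability 0.3). Tier-model weights put most mass on concept-match
    quality, then publication type, then citations.
    """

    vocab_size: int = 2000
    n_docs: int = 5000
    n_topics: int = 10
    n_bearing_per_topic: int = 50
    synonyms_per_concept: int = 2
    substitution_rate: float = 0.3
    disease_present_rate: float = 0.9
    gene_present_rate: float = 0.7
    title_len: int = 8
    abstract_len: int = 40
    match_weight: float = 3.0
    type_weight: float = 1.2
    citation_weight: float = 0.6
    citation_log_mean: float = 1.5
    citation_log_sigma: float = 1.2
    pub_type_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PUB_TYPE_FREQS)
    )
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "disease_present_rate", "gene_present_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("vocab_size", "n_docs", "n_topics", "n_bearing_per_topic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ConceptMention:
    """Ground truth for one topic-bearing document."""

    topic_id: int
    has_disease: bool
    has_gene: bool
    has_treatment: bool

    @property
    def match_quality(self) -> float:
        """Fraction of the topic's three concepts present in the document."""
        return (self.has_disease + self.has_gene + self.has_treatment) / 3.0


class SimulatedExpert:
    """Deterministic 5-tier evidence annotator.

    Tier 0 unless both the disease and the treatment are present (a paper
    that does not discuss the treatment in the disease carries no treatment
    evidence). Otherwise the tier is the clamped rounding of::

        match_weight * (mq - 2/3) * 3 + base
        + type_weight * (ty + 2) / 4 + citation_weight * ct + noise

    which is monotone in match quality, publication-type score, and citation
    quantile. Optional gaussian noise (per-pair, seed-hashed) stays clamped
    to {0..4}.
    """

    def __init__(self, config: GeneratorConfig, noise_sd: float = 0.0) -> None:
        self.config = config
        self.noise_sd = noise_sd

    def tier(
        self,
        match_quality: float,
        has_disease: bool,
        has_treatment: bool,
        ty_score: int,
        ct_quantile: float,
        topic_id: int = 0,
        article_id: str = "",
    ) -> int:
        if not (has_disease and has_treatment):
            return 0
        c = self.config
        raw = (
            1.0
            + (match_quality - 2.0 / 3.0) * c.match_weight
            + c.type_weight * (ty_score + 2) / 4.0
            + c.citation_weight * ct_quantile
        )
        if self.noise_sd > 0:
            digest = zlib.crc32(f"{self.config.seed}:{topic_id}:{article_id}".encode())
            raw += float(np.random.default_rng(digest).normal(0.0, self.noise_sd))
        return int(np.clip(round(raw), 0, 4))


@dataclass
class SyntheticBenchmark:
    """A generated collection plus everything needed to close the loop."""

    config: GeneratorConfig
    articles: list[Article]
    topics: list[Topic]
    synonym_table: SynonymTable
    mentions: dict[str, ConceptMention]  # article id -> ground truth
    qrels: JudgmentSet
    expert: SimulatedExpert
    stats: CorpusStats

    def article_by_id(self, article_id: str) -> Article:
        return self._by_id[article_id]

    def __post_init__(self) -> None:
        self._by_id = {a.id: a for a in self.articles}


def _concept_terms(kind: str, topic_id: int, n_syn: int) -> list[str]:
    """Unique single-token terms: canonical first, then synonyms."""
    return [f"{kind}{topic_id}v0"] + [f"{kind}{topic_id}v{j}" for j in range(1, n_syn + 1)]


def generate_benchmark(config: GeneratorConfig = GeneratorConfig()) -> SyntheticBenchmark:
    """Generate corpus, topics, synonym table, truth judgments, and expert."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array([f"w{i:04d}" for i in range(config.vocab_size)])

    topics = []
    table = SynonymTable()
    disease_terms: dict[int, list[str]] = {}
    gene_terms: dict[int, list[str]] = {}
    for t in range(1, config.n_topics + 1):
        disease_terms[t] = _concept_terms("malady", t, config.synonyms_per_concept)
        gene_terms[t] = _concept_terms("gene", t, config.synonyms_per_concept)
        treatment = f"drug{t}x"
        topics.append(Topic(t, disease_terms[t][0], gene_terms[t][0], treatment))
        table.set(disease_terms[t][0], disease_terms[t])
        table.set(gene_terms[t][0], gene_terms[t])

    n_bearing = config.n_topics * config.n_bearing_per_topic
    if n_bearing > config.n_docs:
        raise ValueError("more bearing documents than documents")
    bearing_slots = rng.permutation(config.n_docs)[:n_bearing]
    topic_of_slot = {
        int(slot): (i % config.n_topics) + 1 for i, slot in enumerate(bearing_slots)
    }

    type_labels = list(config.pub_type_freqs)
    type_probs = np.array([config.pub_type_freqs[t] for t in type_labels], dtype=float)
    type_probs = type_probs / type_probs.sum()

    articles: list[Article] = []
    mentions: dict[str, ConceptMention] = {}
    for i in range(config.n_docs):
        article_id = f"{10_000_000 + i}"
        title_toks = list(rng.choice(vocab, size=config.title_len))
        abstract_toks = list(rng.choice(vocab, size=config.abstract_len))

        labels = {type_labels[int(rng.choice(len(type_labels), p=type_probs))]}
        if "journal article" not in labels and rng.random() < 0.3:
            labels.add("journal article")
        if "clinical trial" in labels or "observational study" in labels:
            abstract_toks.append("trial")
        if rng.random() < 0.3:
            abstract_toks.append("patient")
        elif rng.random() < 0.05:
            abstract_toks.append("trial")

        if i in topic_of_slot:
            t = topic_of_slot[i]
            has_d = bool(rng.random() < config.disease_present_rate)
            has_g = bool(rng.random() < config.gene_present_rate)
            if has_d:
                terms = disease_terms[t]
                tok = (
                    terms[0]
                    if rng.random() >= config.substitution_rate
                    else terms[int(rng.integers(1, len(terms)))]
                )
                abstract_toks.append(tok)
                if rng.random() < 0.5:
                    title_toks.append(tok)
            if has_g:
                terms = gene_terms[t]
                tok = (
                    terms[0]
                    if rng.random() >= config.substitution_rate
                    else terms[int(rng.integers(1, len(terms)))]
                )
                abstract_toks.append(tok)
            abstract_toks.append(f"drug{t}x")
            if rng.random() < 0.3:
                title_toks.append(f"drug{t}x")
            mentions[article_id] = ConceptMention(t, has_d, has_g, True)
        elif rng.random() < 0.03:
            # distractor: one stray concept token, never a disease+treatment pair
            t = int(rng.integers(1, config.n_topics + 1))
            stray = f"drug{t}x" if rng.random() < 0.5 else disease_terms[t][0]
            abstract_toks.append(stray)

        citation = int(rng.lognormal(config.citation_log_mean, config.citation_log_sigma))
        articles.append(
            Article(
                id=article_id,
                title=" ".join(title_toks),
                abstract=" ".join(abstract_toks),
                pub_types=frozenset(labels),
                citation_count=citation,
            )
        )

    stats = CorpusStats(articles)
    expert = SimulatedExpert(config)
    by_id = {a.id: a for a in articles}
    qrels = generate_truth_qrels(mentions, expert, by_id, stats)
    return SyntheticBenchmark(config, articles, topics, table, mentions, qrels, expert, stats)


def generate_truth_qrels(
    mentions: Mapping[str, ConceptMention],
    expert: SimulatedExpert,
    articles: Mapping[str, Article],
    stats: CorpusStats,
) -> JudgmentSet:
    """Tier every concept-bearing document with the simulated expert.

    Non-bearing documents are implicitly tier 0 (they carry no entry).
    """
    qrels = JudgmentSet()
    for article_id, m in sorted(mentions.items()):
        a = articles[article_id]
        tier = expert.tier(
            m.match_quality,
            m.has_disease,
            m.has_treatment,
            publication_type_score(a.pub_types),
            stats.citation_quantile(article_id),
            topic_id=m.topic_id,
            article_id=article_id,
        )
        qrels.add(m.topic_id, article_id, tier)
    return qrels


class SimulatedOracle:
    """Annotation oracle backed by the ground truth (optionally noised).

    ``annotate`` returns the truth tier for known pairs and recomputes the
    expert's judgment from document content for pairs outside the truth set
    (which, lacking a disease+treatment mention for that topic, land on 0).
    Deterministic for a fixed benchmark and noise seed.
    """

    def __init__(self, benchmark: SyntheticBenchmark, noise_sd: float = 0.0, seed: int = 0) -> None:
        self.benchmark = benchmark
        self.noise_sd = noise_sd
        self.seed = seed

    def annotate(self, topic: Topic, article: Article) -> int:
        tier = self.benchmark.qrels.get(topic.id, article.id)
        if tier is None:
            tier = self._judge_cold(topic, article)
        if self.noise_sd > 0:
            pair_seed = (self.seed * 1_000_003 + topic.id * 97 + int(article.id)) % (2**31)
            noise = float(np.random.default_rng(pair_seed).normal(0.0, self.noise_sd))
            tier = int(np.clip(round(tier + noise), 0, 4))
        return int(tier)

    def _judge_cold(self, topic: Topic, article: Article) -> int:
        tokens = set(tokenize(article.text))
        has_d = any(s in tokens for s in self.benchmark.synonym_table.expand(topic.disease))
        has_g = any(s in tokens for s in self.benchmark.synonym_table.expand(topic.gene))
        has_t = topic.treatment.lower() in tokens
        mq = (has_d + has_g + has_t) / 3.0
        return self.benchmark.expert.tier(
            mq,
            has_d,
            has_t,
            publication_type_score(article.pub_types),
            self.benchmark.stats.citation_quantile(article.id)
            if article.id in self.benchmark.stats
            else 0.0,
            topic_id=topic.id,
            article_id=article.id,
        )


def make_oracle(
    benchmark: SyntheticBenchmark, noise_sd: float = 0.0, seed: int = 0
) -> SimulatedOracle:
    """Build the annotation oracle for a benchmark (noiseless by default)."""
    return SimulatedOracle(benchmark, noise_sd, seed)
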