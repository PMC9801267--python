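"""Synonym expansion and per-topic boolean query assembly.

Disease and gene terms expand to weighted synonym clauses; treatments are
deliberately not expanded (treatment terms either have no useful synonyms or
are near-ubiquitous). Synonym weights are normalized document frequencies —
``df(s) / max_j df(s_j)`` — so rare variant spellings are down-weighted and
the best-attested synonym carries full weight. The assembled query must match
the disease and the treatment, and should match the gene and a small list of
evidence-flavoured keywords ("trial", "patient") that act as a weak
classifier for evidence-based papers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Topic
from .index import (
    Bm25Params,
    Bool,
    DisMax,
    InvertedIndex,
    Query,
    ScoredHit,
    SynonymClause,
    TermClause,
    execute,
)

#: Retrieval-stage candidate cap per topic.
CANDIDATE_CAP = 10_000


class SynonymTable:
    """Mapping term -> ordered synonyms, with the original term always first."""

    def __init__(self, entries: Mapping[str, Sequence[str]] | None = None) -> None:
        self._entries: dict[str, list[str]] = {}
        if entries:
            for term, synonyms in entries.items():
                self.set(term, synonyms)

    def set(self, term: str, synonyms: Sequence[str]) -> None:
        if not term:
            raise ValueError("term must be non-empty")
        cleaned = [s for s in synonyms if s]
        if len(cleaned) != len(list(synonyms)):
            raise ValueError(f"{term!r}: synonyms must be non-empty strings")
        ordered = [term] + [s for s in cleaned if s != term]
        self._entries[term] = ordered

    def expand(self, term: str) -> list[str]:
        """Synonyms for a term (the term itself first); unknown terms expand to themselves."""
        return list(self._entries.get(term, [term]))

    def __contains__(self, term: str) -> bool:
        return term in self._entries

    def terms(self) -> list[str]:
        return sorted(self._entries)

    @classmethod
    def read(cls, path: str | Path) -> "SynonymTable":
        """Read a two-column delimited file (term<TAB>synonym, repeated rows)."""
        grouped: dict[str, list[str]] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t") if "\t" in line else line.split(",")
                if len(fields) != 2:
                    raise ValueError(f"line {lineno}: expected 2 fields, got {len(fields)}")
                term, synonym = (f.strip() for f in fields)
                grouped.setdefault(term, []).append(synonym)
        table = cls()
        for term, synonyms in grouped.items():
            table.set(term, synonyms)
        return table

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for term in sorted(self._entries):
                for synonym in self._entries[term]:
                    fh.write(f"{term}\t{synonym}\n")


@dataclass(frozen=True)
class WeightedSynonym:
    text: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class RetrieverConfig:
    """Baseline-retriever knobs.

    Defaults follow the engine configuration of the production system:
    ``dis_max`` tie_breaker 0.8, title boosted 3x over abstract, keywords
    "trial" and "patient" as optional should clauses, and a 10,000-document
    candidate cap per topic. ``query_expansion`` exists for ablations.
    """

    tie_breaker: float = 0.8
    title_boost: float = 3.0
    abstract_boost: float = 1.0
    keywords: tuple[str, ...] = ("trial", "patient")
    candidate_cap: int = CANDIDATE_CAP
    query_expansion: bool = True

    def __post_init__(self) -> None:
        if self.title_boost <= 0 or self.abstract_boost <= 0:
            raise ValueError("field boosts must be > 0")
        if self.candidate_cap < 1:
            raise ValueError("candidate cap must be >= 1")
        if not 0.0 <= self.tie_breaker <= 1.0:
            raise ValueError("tie_breaker must be in [0, 1]")


def synonym_weights(synonyms: Sequence[str], index: InvertedIndex) -> list[WeightedSynonym]:
    """Normalized-document-frequency weights: df(s) / max df, all 1 if all df are 0.

    The df of a multiword synonym counts documents containing all its tokens
    in title or abstract. The best-attested synonym gets weight 1; synonyms
    absent from the collection get weight 0 (their clauses can never match).
    """
    if not synonyms:
        raise ValueError("synonyms must be non-empty")
    dfs = [index.document_frequency(s) for s in synonyms]
    max_df = max(dfs)
    if max_df == 0:
        return [WeightedSynonym(s, 1.0) for s in synonyms]
    return [WeightedSynonym(s, df / max_df) for s, df in zip(synonyms, dfs)]


def _concept_dismax(
    weighted: Sequence[WeightedSynonym], config: RetrieverConfig
) -> DisMax:
    """One dis_max over each synonym's title and abstract clauses."""
    clauses = []
    for ws in weighted:
        clauses.append(SynonymClause(ws.text, "title", ws.weight * config.title_boost))
        clauses.append(SynonymClause(ws.text, "abstract", ws.weight * config.abstract_boost))
    return DisMax(tuple(clauses), config.tie_breaker)


def build_topic_query(
    topic: Topic,
    table: SynonymTable,
    index: InvertedIndex,
    config: RetrieverConfig = RetrieverConfig(),
) -> Bool:
    """Assemble the per-topic boolean query.

    must: disease dis_max (expanded), treatment dis_max (never expanded);
    should: gene dis_max (expanded) plus one keyword term clause per field.
    """
    if config.query_expansion:
        disease_syns = synonym_weights(table.expand(topic.disease), index)
        gene_syns = synonym_weights(table.expand(topic.gene), index)
    else:
        disease_syns = [WeightedSynonym(topic.disease, 1.0)]
        gene_syns = [WeightedSynonym(topic.gene, 1.0)]
    treatment = [WeightedSynonym(topic.treatment, 1.0)]

    must = (
        _concept_dismax(disease_syns, config),
        _concept_dismax(treatment, config),
    )
    should: list[Query] = [_concept_dismax(gene_syns, config)]
    for kw in config.keywords:
        should.append(TermClause(kw, "title", 1.0))
        should.append(TermClause(kw, "abstract", 1.0))
    return Bool(must=must, should=tuple(should))


def retrieve_candidates(
    topic: Topic,
    table: SynonymTable,
    index: InvertedIndex,
    config: RetrieverConfig = RetrieverConfig(),
    params: Bm25Params = Bm25Params(),
) -> list[ScoredHit]:
    """Run the assembled topic query, truncated to the candidate cap.

    Each hit's score is the retrieval (``es``) feature used downstream.
    """
    query = build_topic_query(topic, table, index, config)
    return execute(index, query, params, limit=config.candidate_cap)
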