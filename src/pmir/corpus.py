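"""Data model and file IO for articles, topics, relevance judgments, and runs.

Articles carry the four signals the retrieval pipeline consumes: free text
(title + abstract), MEDLINE publication-type labels, and a citation count.
Judgments are graded on the 5-tier evidence-quality scale (0 = not relevant,
4 = strongest evidence). Runs follow the 6-column TREC submission format and
are capped at 1000 documents per topic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

#: Maximum ranked documents per topic in an emitted run.
RUN_CAP = 1000

#: Number of evidence tiers (labels 0..4).
N_TIERS = 5


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


@dataclass(frozen=True)
class Article:
    """One literature record (PMID-like id, title, abstract, metadata)."""

    id: str
    title: str
    abstract: str = ""
    pub_types: frozenset[str] = frozenset()
    citation_count: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("article id must be non-empty")
        if self.citation_count < 0:
            raise ValueError(f"citation_count must be >= 0, got {self.citation_count}")
        if not isinstance(self.pub_types, frozenset):
            object.__setattr__(self, "pub_types", frozenset(self.pub_types))

    @property
    def text(self) -> str:
        """Concatenated title and abstract (the article side of a text pair)."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class Topic:
    """A precision-medicine query: disease, gene variant, tentative treatment."""

    id: int
    disease: str
    gene: str
    treatment: str

    def __post_init__(self) -> None:
        for name in ("disease", "gene", "treatment"):
            if not getattr(self, name):
                raise ValueError(f"topic {self.id}: {name} must be non-empty")

    @property
    def text(self) -> str:
        """Concatenated disease, gene and treatment (the query side of a text pair)."""
        return f"{self.disease} {self.gene} {self.treatment}"


class JudgmentSet:
    """Graded relevance tiers keyed by (topic id, article id).

    Tiers live in {0..4}; at most one entry per pair. Membership distinguishes
    judged from unjudged documents (an absent pair is unjudged, not tier 0).
    """

    def __init__(self, entries: Mapping[tuple[int, str], int] | None = None) -> None:
        self._entries: dict[tuple[int, str], int] = {}
        if entries:
            for (topic_id, article_id), tier in entries.items():
                self.add(topic_id, article_id, tier)

    def add(self, topic_id: int, article_id: str, tier: int) -> None:
        if not 0 <= tier <= 4:
            raise ValueError(f"tier must be in 0..4, got {tier}")
        key = (int(topic_id), article_id)
        if key in self._entries:
            raise ValueError(f"duplicate judgment for {key}")
        self._entries[key] = int(tier)

    def get(self, topic_id: int, article_id: str, default: int | None = None) -> int | None:
        return self._entries.get((topic_id, article_id), default)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, JudgmentSet) and self._entries == other._entries

    def items(self) -> Iterator[tuple[tuple[int, str], int]]:
        return iter(self._entries.items())

    def topics(self) -> list[int]:
        return sorted({t for t, _ in self._entries})

    def judged_articles(self, topic_id: int) -> dict[str, int]:
        """All judged article ids for one topic, with their tiers."""
        return {a: r for (t, a), r in self._entries.items() if t == topic_id}

    def relevant_count(self, topic_id: int, threshold: int = 1) -> int:
        """Number of judged articles at or above a binarization tier."""
        return sum(1 for (t, _), r in self._entries.items() if t == topic_id and r >= threshold)


@dataclass
class RunRanking:
    """An ordered, scored document list for one topic.

    Entries are (article id, rank, score) with ranks consecutive from 1,
    scores non-increasing, unique ids, and at most ``RUN_CAP`` entries.
    """

    topic_id: int
    entries: list[tuple[str, int, float]] = field(default_factory=list)
    tag: str = "pmir"

    def validate(self) -> None:
        if len(self.entries) > RUN_CAP:
            raise ValueError(
                f"topic {self.topic_id}: {len(self.entries)} entries exceed the run cap of {RUN_CAP}"
            )
        seen: set[str] = set()
        prev_score = None
        for i, (article_id, rank, score) in enumerate(self.entries, start=1):
            if rank != i:
                raise ValueError(f"topic {self.topic_id}: rank {rank} at position {i} is not consecutive")
            if article_id in seen:
                raise ValueError(f"topic {self.topic_id}: duplicate article {article_id}")
            seen.add(article_id)
            if prev_score is not None and score > prev_score:
                raise ValueError(f"topic {self.topic_id}: score increases at rank {rank}")
            prev_score = score

    @property
    def article_ids(self) -> list[str]:
        return [a for a, _, _ in self.entries]

    @classmethod
    def from_scores(
        cls, topic_id: int, scores: Mapping[str, float], tag: str = "pmir", cap: int = RUN_CAP
    ) -> "RunRanking":
        """Rank a score table: descending score, ties by ascending article id."""
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]
        return cls(topic_id, [(a, i, s) for i, (a, s) in enumerate(ordered, start=1)], tag)


# ---------------------------------------------------------------------------
# Article collections


def _article_from_record(rec: dict, index: int) -> Article:
    if "id" not in rec:
        raise FormatError(f"record {index}: missing field 'id'")
    if "title" not in rec:
        raise FormatError(f"record {index}: missing field 'title'")
    try:
        return Article(
            id=str(rec["id"]),
            title=str(rec["title"]),
            abstract=str(rec.get("abstract", "")),
            pub_types=frozenset(rec.get("pub_types", ())),
            citation_count=int(rec.get("citation_count", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"record {index}: {exc}") from exc


def read_article_collection(
    path: str | Path,
    dialect: str = "record-lines",
    citation_counts: Mapping[str, int] | None = None,
) -> list[Article]:
    """Read a document collection.

    ``record-lines`` is one JSON object per line with fields id, title,
    abstract, pub_types, citation_count (the latter three optional).
    ``medline-xml`` is a PubmedArticle XML subset; citation counts are not
    part of MEDLINE records and come from the ``citation_counts`` sidecar
    table (missing ids default to 0).
    """
    path = Path(path)
    if dialect == "record-lines":
        articles = []
        with path.open() as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"record {i}: invalid JSON ({exc})") from exc
                articles.append(_article_from_record(rec, i))
    elif dialect == "medline-xml":
        articles = _read_medline_xml(path, citation_counts or {})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    seen: set[str] = set()
    for a in articles:
        if a.id in seen:
            raise FormatError(f"duplicate article id {a.id!r}")
        seen.add(a.id)
    return articles


def _read_medline_xml(path: Path, citation_counts: Mapping[str, int]) -> list[Article]:
    tree = etree.parse(str(path))
    articles = []
    for i, node in enumerate(tree.iter("PubmedArticle")):
        pmid = node.findtext(".//PMID")
        if not pmid:
            raise FormatError(f"record {i}: missing field 'PMID'")
        title = node.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            t.strip() for t in (el.text or "" for el in node.iter("AbstractText")) if t.strip()
        )
        pub_types = frozenset(
            (el.text or "").strip() for el in node.iter("PublicationType") if (el.text or "").strip()
        )
        articles.append(
            Article(
                id=pmid,
                title=title,
                abstract=abstract,
                pub_types=pub_types,
                citation_count=int(citation_counts.get(pmid, 0)),
            )
        )
    return articles


def write_article_collection(articles: Iterable[Article], path: str | Path) -> None:
    """Write articles in the record-lines dialect (one JSON object per line)."""
    with Path(path).open("w") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {
                        "id": a.id,
                        "title": a.title,
                        "abstract": a.abstract,
                        "pub_types": sorted(a.pub_types),
                        "citation_count": a.citation_count,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Topics


def read_topics(path: str | Path) -> list[Topic]:
    """Read topics from tab- or comma-delimited id/disease/gene/treatment lines."""
    topics = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) != 4:
                raise FormatError(f"line {lineno}: expected 4 fields, got {len(fields)}")
            raw_id, disease, gene, treatment = (f.strip() for f in fields)
            try:
                topic_id = int(raw_id)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: topic id {raw_id!r} is not an integer") from exc
            try:
                topics.append(Topic(topic_id, disease, gene, treatment))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return topics


def write_topics(topics: Iterable[Topic], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in topics:
            fh.write(f"{t.id}\t{t.disease}\t{t.gene}\t{t.treatment}\n")


# ---------------------------------------------------------------------------
# Qrels


def read_qrels(path: str | Path) -> JudgmentSet:
    """Read a TREC qrels file: whitespace-delimited ``topic 0 docid tier``."""
    judgments = JudgmentSet()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"line {lineno}: expected 4 fields, got {len(fields)}")
            topic_id, _, article_id, tier = fields
            try:
                judgments.add(int(topic_id), article_id, int(tier))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return judgments


def write_qrels(judgments: JudgmentSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for (topic_id, article_id), tier in sorted(judgments.items()):
            fh.write(f"{topic_id} 0 {article_id} {tier}\n")


# ---------------------------------------------------------------------------
# Runs


def write_run(rankings: Sequence[RunRanking], path: str | Path, tag: str | None = None) -> None:
    """Write rankings as a TREC run file: ``topic Q0 docid rank score tag``.

    Scores are written with 9 significant digits so a read/write cycle
    preserves them well beyond the 6 significant digits the format requires.
    """
    for r in rankings:
        r.validate()
    with Path(path).open("w") as fh:
        for r in sorted(rankings, key=lambda r: r.topic_id):
            run_tag = tag or r.tag
            for article_id, rank, score in r.entries:
                fh.write(f"{r.topic_id} Q0 {article_id} {rank} {score:.9g} {run_tag}\n")


def read_run(path: str | Path) -> list[RunRanking]:
    by_topic: dict[int, RunRanking] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"line {lineno}: expected 6 fields, got {len(fields)}")
            topic_id, _, article_id, rank, score, run_tag = fields
            ranking = by_topic.setdefault(int(topic_id), RunRanking(int(topic_id), [], run_tag))
            ranking.entries.append((article_id, int(rank), float(score)))
    rankings = [by_topic[t] for t in sorted(by_topic)]
    for r in rankings:
        r.entries.sort(key=lambda e: e[1])
        r.validate()
    return rankings
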