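"""End-to-end orchestration: retrieve -> rerank -> active loop -> evaluate.

Retrieval happens once per topic (capped at 10,000 candidates) and the
candidate pool is cached; reranking and the active-learning loop permute the
cached pool, never re-retrieve. Baseline run files keep the top 1000 by
retrieval score.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .active import ActiveLearningSession, LoopConfig, LoopResult, Oracle, run_loop
from .corpus import RUN_CAP, Article, JudgmentSet, RunRanking, Topic
from .expansion import RetrieverConfig, SynonymTable, retrieve_candidates
from .index import Bm25Params, InvertedIndex, ScoredHit
from .rerank import (
    CorpusStats,
    FeatureVector,
    HashedBowRidgeScorer,
    LexicalOverlapScorer,
    TrainableScorer,
    extract_features,
    get_preset,
    rerank,
)


@dataclass
class BaselineResult:
    """Cached retrieval output: per-topic candidates plus the es-ranked run."""

    index: InvertedIndex
    candidates: dict[int, list[ScoredHit]]
    rankings: list[RunRanking]


def run_baseline(
    articles: Sequence[Article],
    topics: Sequence[Topic],
    table: SynonymTable,
    config: RetrieverConfig = RetrieverConfig(),
    params: Bm25Params = Bm25Params(),
    tag: str = "baseline",
    index: InvertedIndex | None = None,
) -> BaselineResult:
    """Retrieve candidates for every topic and rank the top 1000 by es score."""
    index = index or InvertedIndex(articles)
    candidates: dict[int, list[ScoredHit]] = {}
    rankings: list[RunRanking] = []
    for topic in topics:
        hits = retrieve_candidates(topic, table, index, config, params)
        candidates[topic.id] = hits
        entries = [(h.article_id, i, h.score) for i, h in enumerate(hits[:RUN_CAP], start=1)]
        ranking = RunRanking(topic.id, entries, tag)
        ranking.validate()
        rankings.append(ranking)
    return BaselineResult(index, candidates, rankings)


def build_features(
    topics: Sequence[Topic],
    candidates: Mapping[int, Sequence[ScoredHit]],
    articles: Mapping[str, Article],
    stats: CorpusStats,
    pb_scorer: TrainableScorer | None = None,
) -> dict[int, dict[str, FeatureVector]]:
    """Feature vectors for every (topic, candidate) pair in the pool."""
    pb_scorer = pb_scorer or LexicalOverlapScorer()
    features: dict[int, dict[str, FeatureVector]] = {}
    for topic in topics:
        features[topic.id] = {
            hit.article_id: extract_features(
                topic, hit, articles[hit.article_id], pb_scorer, stats
            )
            for hit in candidates.get(topic.id, ())
        }
    return features


def rerank_all(
    features: Mapping[int, Mapping[str, FeatureVector]],
    preset: str,
    lr_model=None,
    fb_scores: Mapping[int, Mapping[str, float]] | None = None,
) -> list[RunRanking]:
    """Apply one preset to every topic's candidate features."""
    return [
        rerank(
            topic_id,
            features[topic_id],
            preset,
            lr_model=lr_model,
            fb_scores=(fb_scores or {}).get(topic_id),
        )
        for topic_id in sorted(features)
    ]


@dataclass
class FullRunResult:
    baseline: BaselineResult
    loop: LoopResult
    rankings: list[RunRanking]


def run_full(
    articles: Sequence[Article],
    topics: Sequence[Topic],
    table: SynonymTable,
    oracle: Oracle,
    retriever_config: RetrieverConfig = RetrieverConfig(),
    loop_config: LoopConfig = LoopConfig(),
    truth_qrels: JudgmentSet | None = None,
    scorer: TrainableScorer | None = None,
    index: InvertedIndex | None = None,
) -> FullRunResult:
    """Retrieve, run the expert-in-the-loop stage, and rerank with its preset.

    Presets with a nonzero trained-scorer weight require the oracle; the
    loop's final rankings are the run output.
    """
    preset = get_preset(loop_config.preset)
    if preset.w_fb != 0.0 and oracle is None:
        raise ValueError(f"preset {preset.name!r} requires an annotation oracle")
    baseline = run_baseline(articles, topics, table, retriever_config, index=index)
    by_id = {a.id: a for a in articles}
    stats = CorpusStats(articles)
    features = build_features(topics, baseline.candidates, by_id, stats)
    session = ActiveLearningSession(
        topics,
        baseline.candidates,
        by_id,
        features,
        scorer or HashedBowRidgeScorer(),
        loop_config,
        truth_qrels=truth_qrels,
    )
    loop = run_loop(session, oracle)
    rankings = [loop.rankings[t] for t in sorted(loop.rankings)]
    return FullRunResult(baseline, loop, rankings)


def write_manifest(path: str | Path, seed: int, config_repr: str) -> None:
    """Record the run's seed and a hash of its configuration."""
    digest = hashlib.sha256(config_repr.encode()).hexdigest()[:16]
    Path(path).write_text(
        json.dumps({"seed": seed, "config_sha256": digest, "config": config_repr}, indent=2)
        + "\n"
    )
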