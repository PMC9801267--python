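"""Expert-in-the-loop top-1 active learning over a fixed candidate pool.

Each iteration annotates the highest-ranked not-yet-annotated candidate of
every topic (top-1 active feedback), refits the trainable text-pair scorer —
and, by default, the linear feature model — on *all* annotations collected so
far, and re-ranks every topic's candidates with the full combiner. Retrieval
stays outside the loop: iterations re-rank a cached candidate pool.

The loop stops at the iteration budget (default 22) or when the mean
annotated relevance — the running mean of normalized expert labels, an
annotation-quality signal that needs no held-out judgments — has sat below
its running maximum for ``stop_window`` consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import Article, JudgmentSet, RunRanking, Topic
from .evaluation import EXPONENTIAL_GAINS, mean_metric, ndcg_at_k
from .index import ScoredHit
from .rerank import (
    FeatureVector,
    LinearModel,
    Preset,
    TrainableScorer,
    fit_linear_regressor,
    get_preset,
    rerank,
)


@runtime_checkable
class Oracle(Protocol):
    """Annotation source: returns an evidence tier in {0..4} for a pair."""

    def annotate(self, topic: Topic, article: Article) -> int: ...


@dataclass(frozen=True)
class AnnotationRecord:
    topic_id: int
    article_id: str
    tier: int
    iteration: int

    @property
    def label(self) -> float:
        """Normalized training label in [0, 1] (tier / 4)."""
        return self.tier / 4.0


class AnnotationStore:
    """Expert annotations, one per (topic, article), in insertion order."""

    def __init__(self) -> None:
        self.records: list[AnnotationRecord] = []
        self._keys: set[tuple[int, str]] = set()

    def add(self, topic_id: int, article_id: str, tier: int, iteration: int) -> None:
        if not 0 <= tier <= 4:
            raise ValueError(f"tier must be in 0..4, got {tier}")
        key = (topic_id, article_id)
        if key in self._keys:
            raise ValueError(f"pair {key} already annotated")
        if self.records and iteration < self.records[-1].iteration:
            raise ValueError("iteration indices must be non-decreasing")
        self.records.append(AnnotationRecord(topic_id, article_id, tier, iteration))
        self._keys.add(key)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f"{r.topic_id}\t{r.article_id}\t{r.tier}\t{r.iteration}\n")

    @classmethod
    def read(cls, path) -> "AnnotationStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                topic_id, article_id, tier, iteration = line.split("\t")
                store.add(int(topic_id), article_id, int(tier), int(iteration))
        return store


def mean_annotated_relevance(store: AnnotationStore) -> float:
    """Arithmetic mean of the normalized labels collected so far."""
    if not store.records:
        raise ValueError("annotation store is empty")
    return float(np.mean([r.label for r in store.records]))


def select_for_annotation(
    rankings: Mapping[int, RunRanking], store: AnnotationStore, per_topic: int = 1
) -> list[tuple[int, str]]:
    """The highest-ranked unannotated article(s) of each topic.

    Topics whose candidates are all annotated contribute nothing.
    """
    selections = []
    for topic_id in sorted(rankings):
        taken = 0
        for article_id in rankings[topic_id].article_ids:
            if taken == per_topic:
                break
            if (topic_id, article_id) not in store:
                selections.append((topic_id, article_id))
                taken += 1
    return selections


@dataclass(frozen=True)
class LoopConfig:
    """Active-learning loop knobs (defaults follow the production cadence:
    22 iterations, 1 annotation per topic per iteration)."""

    max_iterations: int = 22
    per_topic: int = 1
    stop_window: int = 3
    preset: str = "full-3"
    cold_start_preset: str = "auto-1"
    refit_lr: bool = True
    min_lr_pairs: int = 5

    def __post_init__(self) -> None:
        if self.max_iterations < 0 or self.per_topic < 1 or self.stop_window < 1:
            raise ValueError("loop sizes must be positive (max_iterations may be 0)")


@dataclass
class IterationRecord:
    iteration: int
    new_annotations: int
    mean_annotated_relevance: float
    heldout_ndcg30_exp: float | None = None


@dataclass
class LoopResult:
    history: list[IterationRecord]
    rankings: dict[int, RunRanking]
    store: AnnotationStore
    scorer: TrainableScorer
    lr_model: LinearModel | None
    stopped_early: bool


class ActiveLearningSession:
    """Mutable loop state over a fixed per-topic candidate pool."""

    def __init__(
        self,
        topics: Sequence[Topic],
        candidates: Mapping[int, Sequence[ScoredHit]],
        articles: Mapping[str, Article],
        features: Mapping[int, Mapping[str, FeatureVector]],
        scorer: TrainableScorer,
        config: LoopConfig = LoopConfig(),
        truth_qrels: JudgmentSet | None = None,
    ) -> None:
        self.topics = {t.id: t for t in topics}
        self.candidates = {t: list(hits) for t, hits in candidates.items()}
        self.articles = articles
        self.features = features
        self.scorer = scorer
        self.config = config
        self.truth_qrels = truth_qrels
        self.store = AnnotationStore()
        self.lr_model: LinearModel | None = None
        self.history: list[IterationRecord] = []
        self.preset: Preset = get_preset(config.preset)
        # cold start: no fitted scorer yet, rank with the automatic combiner
        cold = get_preset(config.cold_start_preset)
        self.rankings: dict[int, RunRanking] = {
            t: rerank(t, self.features[t], cold) for t in self.topics
        }

    # -- helpers ------------------------------------------------------------

    def _training_triples(self) -> list[tuple[str, str, float]]:
        return [
            (self.topics[r.topic_id].text, self.articles[r.article_id].text, r.label)
            for r in self.store.records
        ]

    def _refit_lr(self) -> None:
        if not self.config.refit_lr or len(self.store) < self.config.min_lr_pairs:
            return
        x = np.stack(
            [self.features[r.topic_id][r.article_id].as_array() for r in self.store.records]
        )
        y = [r.label for r in self.store.records]
        self.lr_model = fit_linear_regressor(x, y)

    def _fb_scores(self, topic_id: int) -> dict[str, float]:
        topic_text = self.topics[topic_id].text
        return {
            a: self.scorer.score(topic_text, self.articles[a].text)
            for a in self.features[topic_id]
        }

    def heldout_ndcg(self) -> float | None:
        if self.truth_qrels is None:
            return None
        return mean_metric(
            list(self.rankings.values()),
            self.truth_qrels,
            lambda r, q: ndcg_at_k(r, q, EXPONENTIAL_GAINS, 30),
        )

    # -- one iteration ------------------------------------------------------

    def run_iteration(self, oracle: Oracle) -> IterationRecord:
        """Annotate top-1 per topic, refit on all annotations, re-rank."""
        iteration = len(self.history) + 1
        selections = select_for_annotation(self.rankings, self.store, self.config.per_topic)
        for topic_id, article_id in selections:
            try:
                tier = oracle.annotate(self.topics[topic_id], self.articles[article_id])
            except Exception as exc:
                raise RuntimeError(
                    f"oracle failed on topic {topic_id}, article {article_id}"
                ) from exc
            self.store.add(topic_id, article_id, tier, iteration)
        if selections:
            self.scorer.fit(self._training_triples())
            self._refit_lr()
            self.rankings = {
                t: rerank(
                    t,
                    self.features[t],
                    self.preset,
                    lr_model=self.lr_model,
                    fb_scores=self._fb_scores(t),
                )
                for t in self.topics
            }
        record = IterationRecord(
            iteration=iteration,
            new_annotations=len(selections),
            mean_annotated_relevance=(
                mean_annotated_relevance(self.store) if len(self.store) else 0.0
            ),
            heldout_ndcg30_exp=self.heldout_ndcg(),
        )
        self.history.append(record)
        return record


def run_loop(
    session: ActiveLearningSession, oracle: Oracle, config: LoopConfig | None = None
) -> LoopResult:
    """Iterate until the budget is spent or the stop rule fires.

    Stop rule: the mean annotated relevance has been strictly below its
    running maximum for ``stop_window`` consecutive iterations — once the
    loop can only surface documents worse than the best it has seen, further
    annotation stops paying.
    """
    config = config or session.config
    running_max = -np.inf
    decline_streak = 0
    stopped_early = False
    for _ in range(config.max_iterations):
        record = session.run_iteration(oracle)
        if record.new_annotations == 0:
            break
        m = record.mean_annotated_relevance
        if m < running_max:
            decline_streak += 1
        else:
            decline_streak = 0
            running_max = m
        if decline_streak >= config.stop_window:
            stopped_early = True
            break
    return LoopResult(
        history=session.history,
        rankings=session.rankings,
        store=session.store,
        scorer=session.scorer,
        lr_model=session.lr_model,
        stopped_early=stopped_early,
    )
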