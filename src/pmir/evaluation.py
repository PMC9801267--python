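"""TREC-style retrieval metrics: P@10, R-prec, NDCG, and inferred NDCG.

Graded evidence tiers {0..4} map to gains through either the standard map
(0, 1, 2, 3, 4) or the exponential map (0, 1, 2, 4, 8). DCG discounts rank
``i`` by ``log2(i + 1)`` with no discount at rank 1; the ideal DCG comes from
the best possible reordering of all judged documents for the topic.

Inferred NDCG estimates NDCG under the stratified assessment protocol in
which the top 30 ranks are fully judged and ranks 31-100 are judged for a
random 25% sample. Unjudged sampled-stratum positions are imputed with the
mean gain of the judged documents in that stratum, and the ideal DCG inflates
sampled-stratum gain counts by 1/p. At p = 1 with complete judgments the
estimate coincides exactly with NDCG at the pooled depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import JudgmentSet, RunRanking

#: Tier -> gain maps for the five evidence tiers.
STANDARD_GAINS: dict[int, float] = {0: 0.0, 1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}
EXPONENTIAL_GAINS: dict[int, float] = {0: 0.0, 1: 1.0, 2: 2.0, 3: 4.0, 4: 8.0}

GAIN_MAPS = {"standard": STANDARD_GAINS, "exponential": EXPONENTIAL_GAINS}


def precision_at_k(
    ranking: RunRanking, qrels: JudgmentSet, k: int = 10, threshold: int = 1
) -> float:
    """Fraction of the top k that is judged relevant (tier >= threshold).

    Unjudged documents count as irrelevant; an empty ranking scores 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ranking.entries:
        return 0.0
    hits = 0
    for article_id, rank, _ in ranking.entries[:k]:
        tier = qrels.get(ranking.topic_id, article_id)
        if tier is not None and tier >= threshold:
            hits += 1
    return hits / k


def r_precision(ranking: RunRanking, qrels: JudgmentSet, threshold: int = 1) -> float:
    """Precision at rank R, where R is the topic's number of relevant articles."""
    r = qrels.relevant_count(ranking.topic_id, threshold)
    if r == 0:
        return 0.0
    return precision_at_k(ranking, qrels, k=r, threshold=threshold)


def ndcg_at_k(
    ranking: RunRanking,
    qrels: JudgmentSet,
    gains: Mapping[int, float] = STANDARD_GAINS,
    k: int = 30,
) -> float:
    """Exact NDCG at depth k; unjudged documents contribute gain 0.

    The ideal DCG reorders *all* judged documents for the topic, so a run
    that omits a judged relevant document is penalized.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dcg = 0.0
    for article_id, rank, _ in ranking.entries[:k]:
        tier = qrels.get(ranking.topic_id, article_id)
        if tier is not None:
            dcg += gains[tier] / math.log2(rank + 1)
    judged = qrels.judged_articles(ranking.topic_id)
    ideal_gains = sorted((gains[t] for t in judged.values()), reverse=True)
    idcg = 0.0
    for i, g in enumerate(ideal_gains[:k], start=1):
        idcg += g / math.log2(i + 1)
    return dcg / idcg if idcg > 0 else 0.0


# ---------------------------------------------------------------------------
# Inferred NDCG under stratified sampled judgments


@dataclass
class SampledJudgments:
    """A stratified judgment pool for one ranking.

    Ranks 1..top_depth are fully judged; each rank in
    (top_depth, stratum_hi] is judged independently with probability
    ``rate``. ``judged`` maps pooled article ids to their tiers.
    """

    top_depth: int = 30
    stratum_hi: int = 100
    rate: float = 0.25
    judged: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rate <= 1.0:
            raise ValueError("sampling rate must be in (0, 1]")
        if self.top_depth < 1 or self.stratum_hi <= self.top_depth:
            raise ValueError("need 1 <= top_depth < stratum_hi")


def sample_judgment_pool(
    ranking: RunRanking,
    qrels: JudgmentSet,
    top_depth: int = 30,
    stratum_hi: int = 100,
    rate: float = 0.25,
    seed: int = 0,
) -> SampledJudgments:
    """Draw the stratified pool: full top stratum, Bernoulli(rate) sample below.

    Pooled documents absent from the truth judgments are recorded as tier 0
    (assessed and found not relevant). Deterministic per seed.
    """
    if len(ranking.entries) < top_depth:
        raise ValueError(
            f"ranking has {len(ranking.entries)} entries; need at least top_depth={top_depth}"
        )
    rng = np.random.default_rng(seed)
    judged: dict[str, int] = {}
    for article_id, rank, _ in ranking.entries:
        if rank <= top_depth:
            judged[article_id] = qrels.get(ranking.topic_id, article_id, 0)
        elif rank <= stratum_hi:
            if rng.random() < rate:
                judged[article_id] = qrels.get(ranking.topic_id, article_id, 0)
        else:
            break
    return SampledJudgments(top_depth, stratum_hi, rate, judged, seed)


def inferred_ndcg(
    ranking: RunRanking,
    sampled: SampledJudgments,
    gains: Mapping[int, float] = STANDARD_GAINS,
) -> float:
    """Estimate NDCG at the pooled depth from stratified sampled judgments.

    Estimated DCG: exact sum over the fully judged top stratum, plus the
    sampled stratum with judged positions at their gain and unjudged
    positions at the mean gain of the stratum's judged documents.
    Estimated ideal DCG: judged gains with sampled-stratum counts inflated
    by 1/rate, greedily filling (possibly fractional) rank slots best-first.
    """
    depth = sampled.stratum_hi
    top = sampled.top_depth
    entries = ranking.entries[:depth]
    stratum_judged_gains = [
        gains[sampled.judged[a]] for a, rank, _ in entries if rank > top and a in sampled.judged
    ]
    if any(rank > top and a not in sampled.judged for a, rank, _ in entries):
        if stratum_judged_gains:
            imputed = sum(stratum_judged_gains) / len(stratum_judged_gains)
        else:
            warnings.warn("no judged documents in the sampled stratum; imputing gain 0")
            imputed = 0.0
    else:
        imputed = 0.0

    dcg = 0.0
    for article_id, rank, _ in entries:
        if rank <= top:
            if article_id in sampled.judged:
                dcg += gains[sampled.judged[article_id]] / math.log2(rank + 1)
        else:
            g = gains[sampled.judged[article_id]] if article_id in sampled.judged else imputed
            dcg += g / math.log2(rank + 1)

    # (gain, weight) pairs: top-stratum judgments count once, sampled-stratum
    # judgments represent 1/rate documents each.
    in_top = {a for a, rank, _ in entries if rank <= top}
    weighted = []
    for article_id, tier in sampled.judged.items():
        w = 1.0 if article_id in in_top else 1.0 / sampled.rate
        weighted.append((gains[tier], w))
    weighted.sort(key=lambda gw: -gw[0])

    idcg = 0.0
    pos = 0.0
    for g, w in weighted:
        end = pos + w
        while pos < min(end, depth):
            boundary = math.floor(pos) + 1.0
            seg_end = min(end, boundary, float(depth))
            seg = seg_end - pos
            rank = int(math.floor(pos)) + 1
            if seg == 1.0:
                idcg += g / math.log2(rank + 1)
            else:
                idcg += g * seg / math.log2(rank + 1)
            pos = seg_end
        pos = end
        if pos >= depth:
            break
    return dcg / idcg if idcg > 0 else 0.0


# ---------------------------------------------------------------------------
# Topic-wise evaluation tables


@dataclass
class MetricResult:
    """Per-topic values of one metric and their arithmetic mean."""

    name: str
    per_topic: dict[int, float]

    @property
    def mean(self) -> float:
        if not self.per_topic:
            return 0.0
        return float(np.mean(list(self.per_topic.values())))


def _metric_fn(name: str, infndcg_rate: float, infndcg_seed: int) -> Callable:
    if name == "p10":
        return lambda r, q: precision_at_k(r, q, k=10)
    if name == "rprec":
        return r_precision
    if name.startswith("ndcg"):
        # e.g. ndcg30-std, ndcg30-exp
        depth_part, _, gain_part = name[4:].partition("-")
        gains = STANDARD_GAINS if gain_part in ("std", "") else EXPONENTIAL_GAINS
        k = int(depth_part)
        return lambda r, q: ndcg_at_k(r, q, gains, k)
    if name == "infndcg":

        def fn(r: RunRanking, q: JudgmentSet) -> float:
            if len(r.entries) < 30:
                return ndcg_at_k(r, q, STANDARD_GAINS, 100)
            pool = sample_judgment_pool(r, q, rate=infndcg_rate, seed=infndcg_seed + r.topic_id)
            return inferred_ndcg(r, pool, STANDARD_GAINS)

        return fn
    raise ValueError(f"unknown metric {name!r}")


def evaluate_runs(
    rankings: Sequence[RunRanking],
    qrels: JudgmentSet,
    metrics: Iterable[str] = ("p10", "rprec", "ndcg30-std", "ndcg30-exp", "infndcg"),
    infndcg_rate: float = 0.25,
    infndcg_seed: int = 0,
) -> pd.DataFrame:
    """Per-topic metric table with a topic-wise mean row (index "mean")."""
    metrics = list(metrics)
    fns = {m: _metric_fn(m, infndcg_rate, infndcg_seed) for m in metrics}
    rows = {r.topic_id: {m: fns[m](r, qrels) for m in metrics} for r in rankings}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.loc["mean"] = table.mean(axis=0)
    table.index.name = "topic"
    return table


def mean_metric(
    rankings: Sequence[RunRanking],
    qrels: JudgmentSet,
    fn: Callable[[RunRanking, JudgmentSet], float],
) -> float:
    """Topic-wise mean of an arbitrary per-ranking metric."""
    values = [fn(r, qrels) for r in rankings]
    return float(np.mean(values)) if values else 0.0
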