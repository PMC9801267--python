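"""Evidence-quality reranking: features, linear model, score combination.

Each (topic, candidate article) pair is described by four features:

``es``
    the retrieval score from the baseline BM25 query;
``pb``
    a pluggable text-pair relevance score in [0, 1] (default: a lexical
    overlap scorer standing in for a relevance model pretrained on earlier
    campaigns' judgments);
``ty``
    a manually rated publication-type evidence score in [-2, 2]
    (meta-analyses and clinical trials high, errata and retractions low);
``ct``
    the article's citation-count quantile within the corpus, a cheap
    community-importance signal.

Two combiners produce the final ranking. *Automatic* presets take a fixed
weighted sum of max-normalized features. *Full* presets combine an ordinary
least-squares regression on the raw features (fitted to expert annotations)
with a trainable text-pair scorer: ``r = w_LR * LR + w_FB * FB``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.linear_model import LinearRegression, Ridge

from .corpus import RUN_CAP, Article, RunRanking, Topic
from .index import ScoredHit, tokenize

#: Manually rated evidence-quality score per MEDLINE publication type.
#: Unknown labels score 0 (treated like a plain journal article).
PUB_TYPE_SCORES: dict[str, int] = {
    "comment": -1,
    "editorial": -1,
    "published erratum": -2,
    "retraction of publication": -2,
    "english abstract": 0,
    "journal article": 0,
    "letter": 0,
    "review": 0,
    "case reports": 1,
    "observational study": 1,
    "clinical trial": 2,
    "meta-analysis": 2,
    "systematic review": 2,
}


def publication_type_score(pub_types: Iterable[str], score_map: Mapping[str, int] | None = None) -> int:
    """Max evidence score over an article's publication-type labels; empty -> 0.

    Max aggregation: an article that is both "journal article" and
    "meta-analysis" scores as its strongest evidence form.
    """
    score_map = PUB_TYPE_SCORES if score_map is None else score_map
    scores = [score_map.get(t.lower(), 0) for t in pub_types]
    return max(scores) if scores else 0


class CorpusStats:
    """Corpus-level citation statistics for the quantile feature."""

    def __init__(self, articles: Iterable[Article]) -> None:
        self._counts = {a.id: a.citation_count for a in articles}
        if not self._counts:
            raise ValueError("corpus must be non-empty")
        self._sorted = np.sort(np.fromiter(self._counts.values(), dtype=np.int64))

    def __contains__(self, article_id: str) -> bool:
        return article_id in self._counts

    def citation_quantile(self, article_id: str) -> float:
        """Empirical CDF value: fraction of articles with count <= this one's."""
        if article_id not in self._counts:
            raise KeyError(f"article {article_id!r} not in corpus statistics")
        count = self._counts[article_id]
        return float(np.searchsorted(self._sorted, count, side="right")) / len(self._sorted)


def citation_quantile(count: int, corpus_counts: Sequence[int]) -> float:
    """Fraction of corpus articles with citation count <= ``count`` (ties count in)."""
    arr = np.asarray(corpus_counts)
    if arr.size == 0:
        raise ValueError("corpus counts must be non-empty")
    return float(np.count_nonzero(arr <= count)) / arr.size


@dataclass(frozen=True)
class FeatureVector:
    es: float
    pb: float
    ty: int
    ct: float

    def __post_init__(self) -> None:
        if self.es < 0:
            raise ValueError("es must be >= 0")
        if not 0.0 <= self.pb <= 1.0:
            raise ValueError("pb must be in [0, 1]")
        if not -2 <= self.ty <= 2:
            raise ValueError("ty must be in [-2, 2]")
        if not 0.0 <= self.ct <= 1.0:
            raise ValueError("ct must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.es, self.pb, self.ty, self.ct], dtype=float)


# ---------------------------------------------------------------------------
# Text-pair scorers


@runtime_checkable
class TrainableScorer(Protocol):
    """Contract for a text-pair evidence scorer with outputs in [0, 1].

    ``fit`` takes (query text, article text, label in [0, 1]) triples; after
    fitting, ``score`` is deterministic for a fixed seed.
    """

    def fit(self, triples: Sequence[tuple[str, str, float]]) -> None: ...

    def score(self, query_text: str, article_text: str) -> float: ...


class LexicalOverlapScorer:
    """Fixed lexical scorer: fraction of distinct query tokens present in the article.

    Serves as the default ``pb`` backend — an untrained, deterministic stand-in
    for a pair-relevance model, adequate wherever topical overlap tracks
    relevance. ``fit`` is a no-op.
    """

    def fit(self, triples: Sequence[tuple[str, str, float]]) -> None:
        return None

    def score(self, query_text: str, article_text: str) -> float:
        q = set(tokenize(query_text))
        if not q:
            return 0.0
        a = set(tokenize(article_text))
        return len(q & a) / len(q)


class ZeroScorer:
    """Always scores 0; useful for ablations and plumbing tests."""

    def fit(self, triples: Sequence[tuple[str, str, float]]) -> None:
        return None

    def score(self, query_text: str, article_text: str) -> float:
        return 0.0


class HashedBowRidgeScorer:
    """Default trainable text-pair scorer: hashed overlap features + ridge.

    Features of a (query, article) pair are hashed counts of the tokens the
    two texts share (the pair-interaction signal) plus the fraction of query
    tokens matched. A ridge-regularized least-squares fit honors the
    mean-squared-error training objective; predictions are clipped to [0, 1].
    Hashing uses crc32, so fits and scores are reproducible across processes
    and independent of training-example order.
    """

    def __init__(self, n_buckets: int = 4096, alpha: float = 1.0) -> None:
        self.n_buckets = n_buckets
        self.alpha = alpha
        self._model: Ridge | None = None

    def _features(self, query_text: str, article_text: str) -> np.ndarray:
        x = np.zeros(self.n_buckets + 1)
        q = set(tokenize(query_text))
        a = set(tokenize(article_text))
        shared = q & a
        for tok in shared:
            x[zlib.crc32(tok.encode()) % self.n_buckets] += 1.0
        x[-1] = len(shared) / len(q) if q else 0.0
        return x

    def fit(self, triples: Sequence[tuple[str, str, float]]) -> None:
        if not triples:
            raise ValueError("cannot fit on an empty training set")
        x = np.stack([self._features(q, a) for q, a, _ in triples])
        y = np.array([label for _, _, label in triples], dtype=float)
        model = Ridge(alpha=self.alpha)
        model.fit(x, y)
        self._model = model

    def score(self, query_text: str, article_text: str) -> float:
        if self._model is None:
            raise RuntimeError("scorer must be fitted before scoring")
        pred = self._model.predict(self._features(query_text, article_text)[None, :])[0]
        return float(np.clip(pred, 0.0, 1.0))


class TransformerPairScorer:
    """Optional transformer reference backend (not exercised by the test suite).

    Fine-tunes a biomedical BERT encoder on [CLS] query [SEP] article pairs
    with a sigmoid regression head under mean-squared error, using Adam with
    learning rate 4e-5, batch size 16, and 10 epochs per fit. Requires the
    ``torch`` and ``transformers`` packages at call time.
    """

    def __init__(
        self,
        model_name: str = "dmis-lab/biobert-base-cased-v1.1",
        learning_rate: float = 4e-5,
        batch_size: int = 16,
        epochs: int = 10,
        seed: int = 0,
    ) -> None:
        self.model_name = model_name
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self._bundle = None

    def _require(self):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError("TransformerPairScorer requires torch and transformers") from exc
        return torch, transformers

    def fit(self, triples: Sequence[tuple[str, str, float]]) -> None:  # pragma: no cover
        torch, transformers = self._require()
        torch.manual_seed(self.seed)
        tokenizer = transformers.AutoTokenizer.from_pretrained(self.model_name)
        model = transformers.AutoModelForSequenceClassification.from_pretrained(
            self.model_name, num_labels=1
        )
        optimizer = torch.optim.Adam(model.parameters(), lr=self.learning_rate)
        model.train()
        for _ in range(self.epochs):
            for start in range(0, len(triples), self.batch_size):
                batch = triples[start : start + self.batch_size]
                enc = tokenizer(
                    [q for q, _, _ in batch],
                    [a for _, a, _ in batch],
                    truncation=True,
                    padding=True,
                    return_tensors="pt",
                )
                labels = torch.tensor([label for _, _, label in batch]).float()
                logits = model(**enc).logits.squeeze(-1)
                loss = torch.nn.functional.mse_loss(torch.sigmoid(logits), labels)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
        model.eval()
        self._bundle = (tokenizer, model)

    def score(self, query_text: str, article_text: str) -> float:  # pragma: no cover
        torch, _ = self._require()
        if self._bundle is None:
            raise RuntimeError("scorer must be fitted before scoring")
        tokenizer, model = self._bundle
        with torch.no_grad():
            enc = tokenizer(query_text, article_text, truncation=True, return_tensors="pt")
            return float(torch.sigmoid(model(**enc).logits.squeeze(-1)))


# ---------------------------------------------------------------------------
# Feature extraction


def extract_features(
    topic: Topic,
    hit: ScoredHit,
    article: Article,
    pb_scorer: TrainableScorer,
    stats: CorpusStats,
) -> FeatureVector:
    """Assemble the (es, pb, ty, ct) vector for one candidate."""
    if article.id not in stats:
        raise KeyError(f"article {article.id!r} not in corpus statistics")
    return FeatureVector(
        es=hit.score,
        pb=pb_scorer.score(topic.text, article.text),
        ty=publication_type_score(article.pub_types),
        ct=stats.citation_quantile(article.id),
    )


# ---------------------------------------------------------------------------
# Linear model


@dataclass(frozen=True)
class LinearModel:
    """OLS coefficients over (es, pb, ty, ct) plus intercept."""

    coef: tuple[float, float, float, float]
    intercept: float

    def predict_one(self, fv: FeatureVector) -> float:
        return float(np.dot(self.coef, fv.as_array()) + self.intercept)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ np.asarray(self.coef) + self.intercept


def fit_linear_regressor(features: np.ndarray, labels: Sequence[float]) -> LinearModel:
    """Ordinary least squares of labels on raw (es, pb, ty, ct) features.

    Rank-deficient designs yield the minimum-norm solution (the underlying
    lstsq solver), not an error. Requires at least 5 training pairs.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError(f"features must be (n, 4), got {x.shape}")
    if len(y) != len(x):
        raise ValueError("features and labels must have equal length")
    if len(y) < 5:
        raise ValueError(f"need at least 5 training pairs, got {len(y)}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("features and labels must be finite")
    reg = LinearRegression()
    reg.fit(x, y)
    return LinearModel(tuple(float(c) for c in reg.coef_), float(reg.intercept_))


# ---------------------------------------------------------------------------
# Score combination


@dataclass(frozen=True)
class Preset:
    """A named weight configuration.

    ``auto`` presets score ``sum_f w_f * f / f_max`` over max-normalized
    features. ``full`` presets score ``w_lr * LR + w_fb * FB``; their
    ``feature_weights`` are the frozen regression coefficients shipped with
    the configuration, used only when no refitted model is supplied.
    """

    name: str
    mode: str  # "auto" | "full"
    feature_weights: tuple[float, float, float, float]
    intercept: float = 0.0
    w_lr: float = 0.0
    w_fb: float = 0.0


_FROZEN_LR = (-0.465, -0.141, -0.617, -0.005)

PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        Preset("auto-1", "auto", (1.0, 0.5, 1.5, 0.0)),
        Preset("auto-2", "auto", (1.0, 0.5, 1.0, 0.0)),
        Preset("full-1", "full", _FROZEN_LR, 0.0, w_lr=1.0, w_fb=1.0),
        Preset("full-2", "full", _FROZEN_LR, 0.0, w_lr=1.0, w_fb=2.0),
        Preset("full-3", "full", _FROZEN_LR, 0.0, w_lr=1.0, w_fb=5.0),
        # feature ablations (automatic mode)
        Preset("es-pb", "auto", (1.0, 1.0, 0.0, 0.0)),
        Preset("es-ty", "auto", (1.0, 0.0, 1.0, 0.0)),
        Preset("es-ct", "auto", (1.0, 0.0, 0.0, 1.0)),
        # combiner ablations
        Preset("lr-only", "full", _FROZEN_LR, 0.0, w_lr=1.0, w_fb=0.0),
        Preset("fb-only", "full", _FROZEN_LR, 0.0, w_lr=0.0, w_fb=1.0),
    ]
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None


def feature_maxima(features: Iterable[FeatureVector]) -> tuple[float, float, float, float]:
    """Per-topic maxima of each feature over a candidate set."""
    arr = np.stack([fv.as_array() for fv in features])
    return tuple(float(v) for v in arr.max(axis=0))


def combine_auto(
    fv: FeatureVector,
    weights: tuple[float, float, float, float],
    maxima: tuple[float, float, float, float],
) -> float:
    """Weighted sum of max-normalized features; zero-maximum terms contribute 0."""
    total = 0.0
    for w, f, m in zip(weights, fv.as_array(), maxima):
        if m != 0.0:
            total += w * f / m
    return total


def combine_full(lr_prediction: float, fb_score: float, w_lr: float, w_fb: float) -> float:
    """Final evidence score ``r = w_LR * LR + w_FB * FB``."""
    return w_lr * lr_prediction + w_fb * fb_score


def rerank(
    topic_id: int,
    features: Mapping[str, FeatureVector],
    preset: Preset | str,
    lr_model: LinearModel | None = None,
    fb_scores: Mapping[str, float] | None = None,
    tag: str | None = None,
    cap: int = RUN_CAP,
) -> RunRanking:
    """Reorder a candidate set by the selected combiner.

    Reranking permutes and truncates the candidate set only; ties break by
    ascending article id. ``full`` presets use the supplied refitted linear
    model when given, else the preset's frozen coefficients, and require
    ``fb_scores`` whenever ``w_fb`` is nonzero.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if not features:
        return RunRanking(topic_id, [], tag or preset.name)
    if preset.mode == "auto":
        maxima = feature_maxima(features.values())
        scores = {a: combine_auto(fv, preset.feature_weights, maxima) for a, fv in features.items()}
    elif preset.mode == "full":
        model = lr_model or LinearModel(preset.feature_weights, preset.intercept)
        if preset.w_fb != 0.0 and fb_scores is None:
            raise ValueError(f"preset {preset.name!r} needs fb_scores (w_fb={preset.w_fb})")
        scores = {}
        for a, fv in features.items():
            fb = fb_scores.get(a, 0.0) if fb_scores else 0.0
            scores[a] = combine_full(model.predict_one(fv), fb, preset.w_lr, preset.w_fb)
    else:  # pragma: no cover - presets are constructed above
        raise ValueError(f"unknown preset mode {preset.mode!r}")
    return RunRanking.from_scores(topic_id, scores, tag or preset.name, cap=cap)
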