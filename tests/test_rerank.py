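"""Reranking features, the least-squares model, and score combination."""

import numpy as np
import pytest

from pmir.corpus import Article, Topic
from pmir.index import ScoredHit
from pmir.rerank import (
    CorpusStats,
    FeatureVector,
    HashedBowRidgeScorer,
    LexicalOverlapScorer,
    ZeroScorer,
    citation_quantile,
    combine_auto,
    combine_full,
    extract_features,
    feature_maxima,
    fit_linear_regressor,
    get_preset,
    publication_type_score,
    rerank,
)


class TestPublicationTypeScore:
    @pytest.mark.parametrize(
        "types,expected",
        [
            ({"meta-analysis"}, 2),
            ({"comment"}, -1),
            ({"retraction of publication"}, -2),
            ({"journal article", "clinical trial"}, 2),  # max aggregation
            ({"comment", "case reports"}, 1),
            (set(), 0),
            ({"some novel label"}, 0),
            ({"Meta-Analysis"}, 2),  # case-insensitive
        ],
    )
    def test_examples(self, types, expected):
        assert publication_type_score(types) == expected


class TestCitationQuantile:
    def test_hand_cdf(self):
        assert citation_quantile(1, [0, 1, 2, 3]) == 0.5

    def test_corpus_maximum_is_one(self):
        assert citation_quantile(3, [0, 1, 2, 3]) == 1.0

    def test_point_mass_gives_one_everywhere(self):
        assert citation_quantile(7, [7, 7, 7]) == 1.0

    def test_stats_object_matches_function(self):
        articles = [Article(id=f"D{i}", title="t", citation_count=c) for i, c in enumerate([0, 5, 5, 9])]
        stats = CorpusStats(articles)
        assert stats.citation_quantile("D1") == citation_quantile(5, [0, 5, 5, 9]) == 0.75


class TestExtractFeatures:
    TOPIC = Topic(1, "melanoma", "braf", "dabrafenib")

    def _stats(self):
        return CorpusStats(
            [
                Article(id="D1", title="melanoma study", abstract="braf", citation_count=10),
                Article(id="D2", title="other", citation_count=0),
            ]
        )

    def test_zero_scorer_gives_zero_pb(self):
        article = Article(id="D1", title="melanoma study", abstract="braf",
                          pub_types=frozenset({"review"}), citation_count=10)
        fv = extract_features(self.TOPIC, ScoredHit("D1", 3.5), article, ZeroScorer(), self._stats())
        assert fv == FeatureVector(es=3.5, pb=0.0, ty=0, ct=1.0)

    def test_lexical_overlap_pb(self):
        article = Article(id="D1", title="melanoma study", abstract="braf", citation_count=10)
        fv = extract_features(self.TOPIC, ScoredHit("D1", 1.0), article, LexicalOverlapScorer(), self._stats())
        assert fv.pb == pytest.approx(2 / 3)  # melanoma, braf of 3 query tokens

    def test_unknown_article_rejected(self):
        article = Article(id="D9", title="x")
        with pytest.raises(KeyError):
            extract_features(self.TOPIC, ScoredHit("D9", 1.0), article, ZeroScorer(), self._stats())


class TestLinearRegressor:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        x = np.column_stack(
            [rng.uniform(0, 10, 50), rng.uniform(0, 1, 50), rng.integers(-2, 3, 50), rng.uniform(0, 1, 50)]
        )
        y = 2.0 * x[:, 0]
        model = fit_linear_regressor(x, y)
        assert np.allclose(model.coef, (2, 0, 0, 0), atol=1e-8)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_constant_labels(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(20, 4))
        model = fit_linear_regressor(x, np.full(20, 0.7))
        assert np.allclose(model.coef, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(0.7, abs=1e-10)

    def test_rank_deficient_design_gives_minimum_norm_fit(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(0, 1, 30)
        x = np.column_stack([col, col, np.zeros(30), np.zeros(30)])  # duplicated + dead columns
        y = 3.0 * col
        model = fit_linear_regressor(x, y)
        assert np.all(np.isfinite(model.coef))
        assert np.allclose(model.predict(x), y, atol=1e-8)
        # minimum-norm solution splits the weight across duplicate columns
        assert model.coef[0] == pytest.approx(model.coef[1], abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_linear_regressor(np.ones((4, 4)), [1, 2, 3, 4])

    def test_noisy_recovery_within_sampling_error(self):
        rng = np.random.default_rng(3)
        true = np.array([0.8, -0.3, 0.1, 0.5])
        x = rng.normal(size=(500, 4))
        y = x @ true + 0.2 + rng.normal(0, 0.05, 500)
        model = fit_linear_regressor(x, y)
        assert np.allclose(model.coef, true, atol=0.02)


class TestCombiners:
    def test_auto_all_features_at_maxima(self):
        preset = get_preset("auto-1")
        fv = FeatureVector(es=5.0, pb=0.8, ty=2, ct=0.9)
        maxima = (5.0, 0.8, 2.0, 0.9)
        assert combine_auto(fv, preset.feature_weights, maxima) == pytest.approx(3.0)

    def test_zero_weight_feature_cannot_reorder(self):
        preset = get_preset("auto-1")  # w_ct = 0
        maxima = (1.0, 1.0, 2.0, 1.0)
        lo = combine_auto(FeatureVector(1.0, 0.5, 1, 0.0), preset.feature_weights, maxima)
        hi = combine_auto(FeatureVector(1.0, 0.5, 1, 1.0), preset.feature_weights, maxima)
        assert lo == hi

    def test_zero_maximum_term_contributes_nothing(self):
        fv = FeatureVector(es=1.0, pb=0.0, ty=0, ct=0.5)
        assert combine_auto(fv, (1.0, 1.0, 1.0, 0.0), (2.0, 0.0, 0.0, 1.0)) == pytest.approx(0.5)

    def test_publication_type_monotonicity(self):
        maxima = (1.0, 1.0, 2.0, 1.0)
        comment = combine_auto(FeatureVector(1.0, 0.5, -1, 0.5), (1.0, 0.5, 1.5, 0.0), maxima)
        meta = combine_auto(FeatureVector(1.0, 0.5, 2, 0.5), (1.0, 0.5, 1.5, 0.0), maxima)
        assert meta > comment

    def test_full_combiner_hand_value(self):
        preset = get_preset("full-3")
        assert combine_full(0.2, 0.5, preset.w_lr, preset.w_fb) == pytest.approx(2.7)

    @pytest.mark.parametrize("w_lr,w_fb,expected", [(1.0, 0.0, 0.2), (0.0, 1.0, 0.5)])
    def test_degenerate_weights(self, w_lr, w_fb, expected):
        assert combine_full(0.2, 0.5, w_lr, w_fb) == pytest.approx(expected)


class TestRerank:
    def _features(self, n):
        rng = np.random.default_rng(7)
        return {
            f"D{i:04d}": FeatureVector(
                es=float(rng.uniform(0, 10)),
                pb=float(rng.uniform(0, 1)),
                ty=int(rng.integers(-2, 3)),
                ct=float(rng.uniform(0, 1)),
            )
            for i in range(n)
        }

    def test_order_matches_brute_force_sort(self):
        features = self._features(50)
        preset = get_preset("auto-2")
        ranking = rerank(1, features, preset)
        maxima = feature_maxima(features.values())
        expected = sorted(
            features, key=lambda a: (-combine_auto(features[a], preset.feature_weights, maxima), a)
        )
        assert ranking.article_ids == expected

    def test_ties_break_by_ascending_id(self):
        features = {a: FeatureVector(1.0, 0.5, 1, 0.5) for a in ("B", "A", "C")}
        ranking = rerank(1, features, "auto-1")
        assert ranking.article_ids == ["A", "B", "C"]

    def test_truncates_to_run_cap(self):
        ranking = rerank(1, self._features(1500), "auto-1")
        assert len(ranking.entries) == 1000
        ranking.validate()

    def test_never_invents_documents(self):
        features = self._features(30)
        ranking = rerank(1, features, "es-ty")
        assert set(ranking.article_ids) <= set(features)

    def test_unknown_preset_lists_known_ones(self):
        with pytest.raises(KeyError, match="auto-1"):
            rerank(1, self._features(3), "no-such-preset")

    def test_full_preset_requires_fb_scores(self):
        with pytest.raises(ValueError, match="fb_scores"):
            rerank(1, self._features(3), "full-3")

    def test_full_preset_with_frozen_coefficients(self):
        features = self._features(10)
        fb = {a: 0.0 for a in features}
        ranking = rerank(1, features, "full-1", fb_scores=fb)
        model_coef = np.array(get_preset("full-1").feature_weights)
        expected = sorted(features, key=lambda a: (-float(model_coef @ features[a].as_array()), a))
        assert ranking.article_ids == expected


class TestHashedBowRidgeScorer:
    TRIPLES = [
        ("melanoma braf dabrafenib", "melanoma braf trial dabrafenib", 1.0),
        ("melanoma braf dabrafenib", "melanoma only mention", 0.5),
        ("melanoma braf dabrafenib", "unrelated words here", 0.0),
        ("lung egfr erlotinib", "egfr erlotinib lung cohort", 1.0),
        ("lung egfr erlotinib", "nothing shared", 0.0),
    ]

    def test_outputs_clipped_to_unit_interval(self):
        scorer = HashedBowRidgeScorer()
        scorer.fit(self.TRIPLES)
        for q, a, _ in self.TRIPLES:
            assert 0.0 <= scorer.score(q, a) <= 1.0

    def test_fit_is_order_independent(self):
        a, b = HashedBowRidgeScorer(), HashedBowRidgeScorer()
        a.fit(self.TRIPLES)
        b.fit(list(reversed(self.TRIPLES)))
        for q, t, _ in self.TRIPLES:
            assert a.score(q, t) == pytest.approx(b.score(q, t), abs=1e-9)

    def test_learns_overlap_signal(self):
        scorer = HashedBowRidgeScorer()
        scorer.fit(self.TRIPLES)
        high = scorer.score("melanoma braf dabrafenib", "melanoma braf dabrafenib study")
        low = scorer.score("melanoma braf dabrafenib", "completely different text")
        assert high > low

    def test_unfitted_scorer_refuses(self):
        with pytest.raises(RuntimeError):
            HashedBowRidgeScorer().score("q", "a")
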