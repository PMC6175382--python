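import numpy as np
import pytest
from scipy.optimize import minimize

from screenprio.corpus import build_vocabulary
from screenprio.errors import (
    ColdStartError,
    ConfigurationError,
    DecisionConflictError,
    QueryParseError,
)
from screenprio.features import build_features, fit_tfidf
from screenprio.prioritiser import (
    ClassifierConfig,
    CollectionIndex,
    LinearModel,
    ScreeningSession,
    confidence,
    keyword_filter,
    predict,
    rank,
    train,
)


class TestTrain:
    def test_separable_toy_set_reaches_full_accuracy(self):
        X = np.array([[1.0, 1.0], [2.0, 1.5], [-1.0, -1.0], [-2.0, -1.5]])
        y = np.array([1, 1, -1, -1])
        model = train(X, y)
        preds = np.sign(model.decision_value(X))
        np.testing.assert_array_equal(preds, y)

    def test_objective_matches_generic_qp_oracle(self, rng):
        # independent check of the squared-hinge primal objective:
        # f(w,b) = 0.5(||w||^2 + b^2) + C sum max(0, 1 - y(w.x + b))^2
        X = rng.normal(size=(20, 5))
        y = np.where(rng.random(20) < 0.5, 1, -1)
        y[0], y[1] = 1, -1  # both classes present
        C = 1.0

        def objective(wb):
            w, b = wb[:5], wb[5]
            margins = y * (X @ w + b)
            hinge = np.maximum(0.0, 1.0 - margins)
            return 0.5 * (w @ w + b * b) + C * np.sum(hinge**2)

        oracle = minimize(objective, np.zeros(6), method="BFGS",
                          options={"gtol": 1e-10})
        model = train(X, y, ClassifierConfig(cost_C=C, tolerance_eps=1e-8))
        ours = objective(np.concatenate([model.weights, [model.bias]]))
        assert ours == pytest.approx(oracle.fun, abs=1e-3)

    def test_duplicating_a_slack_point_leaves_direction_unchanged(self):
        X = np.array([[2.0, 2.0], [3.0, 3.0], [-2.0, -2.0], [-3.0, -3.0]])
        y = np.array([1, 1, -1, -1])
        config = ClassifierConfig(cost_C=100.0, tolerance_eps=1e-10)
        base = train(X, y, config)
        X2 = np.vstack([X, [3.0, 3.0]])  # duplicate an include off the margin
        y2 = np.append(y, 1)
        dup = train(X2, y2, config)
        cos = (base.weights @ dup.weights) / (
            np.linalg.norm(base.weights) * np.linalg.norm(dup.weights)
        )
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_single_class_raises_cold_start(self):
        with pytest.raises(ColdStartError):
            train(np.eye(3), np.array([1, 1, 1]))


class TestConfidence:
    def test_zero_margin_gives_half(self):
        model = LinearModel(weights=np.array([1.0, -1.0]), bias=0.0)
        assert confidence(model, np.array([[1.0, 1.0]])) == pytest.approx(0.5)

    def test_log3_margin_gives_three_quarters(self):
        model = LinearModel(weights=np.array([np.log(3.0)]), bias=0.0)
        assert confidence(model, np.array([[1.0]])) == pytest.approx(0.75)

    def test_strictly_increasing_in_margin(self):
        model = LinearModel(weights=np.array([1.0]), bias=0.0)
        xs = np.linspace(-5, 5, 21).reshape(-1, 1)
        conf = confidence(model, xs)
        assert np.all(np.diff(conf) > 0)


class TestPredict:
    def setup_method(self):
        self.model = LinearModel(weights=np.array([1.0]), bias=0.0)

    def test_above_threshold_includes(self):
        x = np.array([[np.log(0.6 / 0.4)]])  # confidence 0.6
        assert predict(self.model, x, threshold=0.5) == "include"

    def test_boundary_confidence_counts_as_include(self):
        assert predict(self.model, np.array([[0.0]]), threshold=0.5) == "include"

    def test_threshold_one_excludes_everything_short_of_certainty(self):
        assert predict(self.model, np.array([[10.0]]), threshold=1.0) == "exclude"


class TestRank:
    def test_distinct_confidences_sorted_strictly(self):
        conf = {"a": 0.9, "b": 0.1, "c": 0.5}
        r = rank(["a", "b", "c"], conf, screened=set())
        assert r.ids == ["a", "c", "b"]

    def test_ties_broken_by_reference_id(self):
        conf = {"z": 0.5, "a": 0.5, "m": 0.5}
        r = rank(["z", "a", "m"], conf, screened=set())
        assert r.ids == ["a", "m", "z"]

    def test_ranking_excludes_screened(self):
        conf = {"a": 0.9, "b": 0.8, "c": 0.7}
        r = rank(["a", "b", "c"], conf, screened={"a"})
        assert r.ids == ["b", "c"]


@pytest.fixture(scope="module")
def fitted_session(small_labelled):
    collection, labels = small_labelled
    vocab = build_vocabulary(collection, min_count=5)
    t = fit_tfidf(collection, vocab, "title")
    a = fit_tfidf(collection, vocab, "abstract")
    feats = build_features(collection, t, a, None)
    return collection, labels, feats


class TestScreeningSession:
    def _session(self, fitted_session, **config):
        collection, labels, feats = fitted_session
        return collection, labels, ScreeningSession(
            collection, feats, ClassifierConfig(**config)
        )

    def test_reminder_after_25_decisions_without_update(self, fitted_session):
        collection, labels, session = self._session(fitted_session)
        for ref_id in collection.ids[:25]:
            session.record_decision(ref_id, "exclude")
        assert session.reminder_due

    def test_retrain_resets_counter(self, fitted_session):
        collection, labels, session = self._session(fitted_session)
        rng = np.random.default_rng(0)
        for ref_id in collection.ids[:60]:
            session.record_decision(ref_id, "include" if labels[ref_id] else "exclude")
        assert session.can_train()
        session.retrain()
        assert session.decisions_since_update == 0
        assert not session.reminder_due

    def test_unknown_id_rejected(self, fitted_session):
        _, _, session = self._session(fitted_session)
        with pytest.raises(ConfigurationError):
            session.record_decision("nope", "include")

    def test_re_deciding_raises_conflict(self, fitted_session):
        collection, _, session = self._session(fitted_session)
        session.record_decision(collection.ids[0], "include")
        with pytest.raises(DecisionConflictError):
            session.record_decision(collection.ids[0], "exclude")
        session.revise_decision(collection.ids[0], "exclude")
        assert session.decisions[collection.ids[0]] == "exclude"

    def test_ranking_before_training_raises(self, fitted_session):
        _, _, session = self._session(fitted_session)
        with pytest.raises(ColdStartError):
            session.ranking()

    def test_retrain_is_idempotent(self, fitted_session):
        collection, labels, session = self._session(fitted_session)
        for ref_id in collection.ids[:80]:
            session.record_decision(ref_id, "include" if labels[ref_id] else "exclude")
        session.retrain()
        first = session.ranking()
        session.retrain()
        assert session.ranking().entries == first.entries

    def test_ranking_is_permutation_of_unscreened(self, fitted_session):
        collection, labels, session = self._session(fitted_session)
        screened = collection.ids[:80]
        for ref_id in screened:
            session.record_decision(ref_id, "include" if labels[ref_id] else "exclude")
        session.retrain()
        ranking = session.ranking()
        assert sorted(ranking.ids) == sorted(set(collection.ids) - set(screened))

    def test_top_of_ranking_is_enriched_in_true_includes(self, fitted_session):
        collection, labels, session = self._session(fitted_session)
        rng = np.random.default_rng(4)
        batch = rng.choice(collection.ids, size=100, replace=False)
        for ref_id in batch:
            session.record_decision(str(ref_id), "include" if labels[str(ref_id)] else "exclude")
        session.retrain()
        top10 = session.ranking().top(10)
        assert sum(labels[i] for i in top10) >= 8

    def test_save_restore_round_trip(self, fitted_session, tmp_path):
        collection, labels, session = self._session(fitted_session)
        for ref_id in collection.ids[:50]:
            session.record_decision(ref_id, "include" if labels[ref_id] else "exclude")
        session.retrain()
        path = session.save(tmp_path / "session.json")
        _, _, fresh = self._session(fitted_session)
        fresh.restore(path)
        assert fresh.decisions == session.decisions
        assert fresh.ranking().entries == session.ranking().entries


@pytest.fixture(scope="module")
def index(toy_collection):
    return CollectionIndex(toy_collection)


class TestKeywordFilter:

    def test_and_semantics(self, index):
        assert keyword_filter(index, "diabetes AND pregnancy") == {"r1", "r2"}

    def test_or_and_not(self, index):
        assert keyword_filter(index, "cycling OR hypertension") == {"r4", "r5", "r6"}
        assert keyword_filter(index, "NOT cycling") == {"r1", "r2", "r3", "r4"}

    def test_lemmatised_matching(self, index):
        # query in plural matches singular occurrences and vice versa
        assert keyword_filter(index, "trial") == {"r3", "r4"}
        assert keyword_filter(index, "trials") == {"r3", "r4"}

    def test_phrase_query(self, index):
        assert keyword_filter(index, '"blood pressure"') == {"r3", "r4"}
        assert keyword_filter(index, '"pressure blood"') == set()

    def test_parentheses_and_precedence(self, index):
        out = keyword_filter(index, "(diabetes OR cycling) AND NOT pregnancy")
        assert out == {"r5", "r6"}

    def test_parse_error_carries_position(self, index):
        with pytest.raises(QueryParseError) as err:
            keyword_filter(index, "diabetes AND AND pregnancy")
        assert err.value.position == 13

    def test_unbalanced_parenthesis_rejected(self, index):
        with pytest.raises(QueryParseError):
            keyword_filter(index, "(diabetes")

    def test_topic_filter_uses_argmax_topic(self, toy_collection, small_labelled):
        collection, _ = small_labelled
        from screenprio.corpus import build_vocabulary
        from screenprio.lda import TopicModelParams, fit_lda

        vocab = build_vocabulary(collection, min_count=5)
        model = fit_lda(collection, vocab,
                        TopicModelParams(K=3, n_iterations=60, optimise_interval=0, seed=1))
        index = CollectionIndex(collection, topic_model=model)
        expected = {
            ref_id
            for ref_id, k in zip(model.doc_ids, model.doc_topic.argmax(axis=1))
            if k == 1
        }
        assert keyword_filter(index, "topic:1") == expected
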