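"""Label-powerset transformation and RAKEL ensemble behaviour."""

import numpy as np
import pytest

from predictefc import build_profile, encode_batch
from predictefc.rakel_core import (
    BaseClassifierSpec,
    LabelsetCollection,
    RakelClassifier,
    _LPModel,
    lp_transform,
    normalized_poly_kernel,
    puk_kernel,
    sample_labelsets,
)


class TestSampleLabelsets:
    def test_k_equals_L_gives_full_labelset_copies(self):
        coll = sample_labelsets(L=7, k=7, m=10, seed=0)
        assert all(s == frozenset(range(1, 8)) for s in coll.subsets)
        assert coll.m == 10

    def test_k1_m_equals_L_yields_all_singletons(self):
        coll = sample_labelsets(L=7, k=1, m=7, seed=0)
        assert sorted(next(iter(s)) for s in coll.subsets) == list(range(1, 8))

    @pytest.mark.parametrize("seed", range(10))
    def test_coverage_holds_for_every_sampled_collection(self, seed):
        coll = sample_labelsets(L=7, k=3, m=10, seed=seed)
        covered = set()
        for s in coll.subsets:
            assert len(s) == 3
            covered |= s
        assert covered == set(range(1, 8))

    def test_coverage_impossible_is_error(self):
        with pytest.raises(ValueError, match="coverage impossible"):
            sample_labelsets(L=7, k=2, m=3, seed=0)

    def test_k_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            sample_labelsets(L=7, k=8, m=10, seed=0)

    def test_same_seed_same_collection(self):
        a = sample_labelsets(L=7, k=3, m=10, seed=5)
        b = sample_labelsets(L=7, k=3, m=10, seed=5)
        assert a.subsets == b.subsets

    def test_collection_invariant_enforced(self):
        with pytest.raises(ValueError, match="cover"):
            LabelsetCollection(subsets=(frozenset({1, 2}),), k=2, m=1, L=3, seed=0)


class TestLPTransform:
    def test_basic_projection(self):
        classes, mapping = lp_transform([{1}, {2}, {1}], {1, 2})
        assert mapping.n_classes == 2
        assert classes[0] == classes[2] != classes[1]

    def test_projection_is_set_intersection(self):
        classes, mapping = lp_transform([{1, 3}], {1, 2})
        assert mapping.inverse[int(classes[0])] == (1,)

    def test_empty_projection_is_a_class(self):
        classes, mapping = lp_transform([{3}, {1}], {1, 2})
        assert mapping.inverse[int(classes[0])] == ()
        assert mapping.n_classes == 2

    def test_mapping_is_bijective(self):
        classes, mapping = lp_transform([{1}, {2}, {1, 2}, {3}], {1, 2})
        assert set(mapping.forward.values()) == set(mapping.inverse)
        for ls, c in mapping.forward.items():
            assert mapping.inverse[c] == ls


def _separable_xy(corpus):
    ds, _ = corpus
    prof = build_profile(ds)
    X = encode_batch(ds, prof)
    Y = [ds.labels.labels(p) for p in ds.ids]
    return X, Y


class TestRakelFitPredict:
    def test_rakel_degenerates_to_lp_when_k_equals_L(self, separable_corpus, rf_small):
        """k=L, m=1: the ensemble is exactly one LP classifier over all labels."""
        X, Y = _separable_xy(separable_corpus)
        model = RakelClassifier(L=7, k=7, m=1, base=rf_small, seed=3).fit(X, Y)
        # independent plain-LP oracle sharing the derived seed
        classes, mapping = lp_transform(Y, frozenset(range(1, 8)))
        est = rf_small.build(model._child_seeds(2)[1]).fit(X, classes)
        lp_pred = [frozenset(mapping.inverse[int(c)]) for c in est.predict(X)]
        assert model.predict(X) == lp_pred

    def test_refit_same_seed_is_identical(self, separable_corpus, rf_small):
        X, Y = _separable_xy(separable_corpus)
        a = RakelClassifier(L=7, k=3, m=10, base=rf_small, seed=9).fit(X, Y)
        b = RakelClassifier(L=7, k=3, m=10, base=rf_small, seed=9).fit(X, Y)
        assert a.labelsets_.subsets == b.labelsets_.subsets
        assert a.predict(X) == b.predict(X)
        np.testing.assert_array_equal(a.predict_scores(X), b.predict_scores(X))

    def test_training_subset_accuracy_on_separable_corpus(self, separable_corpus, rf_small):
        X, Y = _separable_xy(separable_corpus)
        model = RakelClassifier(L=7, k=7, m=10, base=rf_small, seed=1).fit(X, Y)
        pred = model.predict(X)
        exact = np.mean([p == y for p, y in zip(pred, Y)])
        assert exact >= 0.99

    def test_predictions_never_empty(self, noisy_corpus, rf_small):
        X, Y = _separable_xy(noisy_corpus)
        model = RakelClassifier(L=7, k=3, m=10, base=rf_small, seed=2).fit(X, Y)
        assert all(len(p) >= 1 for p in model.predict(X))

    def test_hard_scores_are_vote_fractions(self, noisy_corpus, rf_small):
        X, Y = _separable_xy(noisy_corpus)
        model = RakelClassifier(L=7, k=3, m=10, base=rf_small, seed=2).fit(X, Y)
        scores = model.predict_scores(X)
        c = model._coverage_counts()
        assert (scores >= 0).all() and (scores <= 1).all()
        # every entry is an integer number of votes over the coverage count
        votes = scores * c[None, :]
        np.testing.assert_allclose(votes, np.round(votes), atol=1e-9)

    def test_column_mismatch_is_error(self, separable_corpus, rf_small):
        X, Y = _separable_xy(separable_corpus)
        model = RakelClassifier(L=7, k=3, m=5, base=rf_small, seed=2).fit(X, Y)
        with pytest.raises(ValueError, match="columns"):
            model.predict(X[:, :3])

    def test_empty_training_labelset_is_error(self, rf_small):
        with pytest.raises(ValueError, match="nonempty"):
            RakelClassifier(L=3, k=2, m=3, base=rf_small, seed=0).fit(
                np.zeros((2, 3)), [{1}, set()]
            )

    def test_single_observed_class_fits_constant_predictor(self, rf_small):
        X = np.random.default_rng(0).random((10, 3))
        model = RakelClassifier(L=3, k=3, m=1, base=rf_small, seed=0).fit(X, [{1, 2}] * 10)
        assert model.predict(X) == [frozenset({1, 2})] * 10


class _StubEstimator:
    """Predicts a fixed LP class for every sample."""

    def __init__(self, cls, n_classes):
        self.cls = cls
        self.classes_ = np.arange(n_classes)

    def predict(self, X):
        return np.full(len(X), self.cls)


def _manual_model(L, lp_specs, threshold=0.5):
    """Assemble a fitted RakelClassifier from (subset, mapping-pairs, vote) specs."""
    from predictefc.rakel_core import LPMapping

    model = RakelClassifier(L=L, k=len(lp_specs[0][0]), m=len(lp_specs), threshold=threshold)
    model.n_features_ = 1
    model.lp_models_ = []
    for subset, labelsets, vote_idx in lp_specs:
        mapping = LPMapping.from_labelsets([tuple(sorted(ls)) for ls in labelsets])
        model.lp_models_.append(
            _LPModel(subset=frozenset(subset), mapping=mapping,
                     estimator=_StubEstimator(vote_idx, mapping.n_classes))
        )
    return model


class TestVoteAggregation:
    def test_two_of_three_votes_crosses_threshold(self):
        """Label 1 covered by 3 subset-models voting (yes, no, yes) -> score 2/3."""
        model = _manual_model(
            3,
            [
                ({1, 2}, [(1,), ()], 0),  # votes {1}
                ({1, 3}, [(1,), ()], 1),  # votes {}
                ({1, 2}, [(1,), ()], 0),  # votes {1}
            ],
        )
        X = np.zeros((1, 1))
        scores = model.predict_scores(X)
        assert scores[0, 0] == pytest.approx(2 / 3)
        assert model.predict(X) == [frozenset({1})]

    def test_all_zero_scores_fall_back_to_lowest_argmax(self):
        model = _manual_model(3, [({1, 2, 3}, [(), (1,)], 0)])
        X = np.zeros((2, 1))
        assert (model.predict_scores(X) == 0).all()
        assert model.predict(X) == [frozenset({1})] * 2

    def test_score_at_threshold_counts_as_positive(self):
        model = _manual_model(
            2,
            [({1, 2}, [(1,), (2,)], 0), ({1, 2}, [(1,), (2,)], 1)],
        )
        # label 1: one yes of two -> exactly 0.5 -> predicted at the default threshold
        assert 1 in model.predict(np.zeros((1, 1)))[0]


class _ProbStub:
    def __init__(self, proba, classes):
        self.proba = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.classes_[np.argmax(self.proba, axis=1)][: len(X)]

    def predict_proba(self, X):
        return np.tile(self.proba, (len(X), 1))


class TestSoftScores:
    def test_probability_mass_summation(self):
        """P({1})=0.7, P({1,2})=0.2, P({})=0.1 -> score(1)=0.9, score(2)=0.2."""
        from predictefc.rakel_core import LPMapping

        mapping = LPMapping.from_labelsets([(1,), (1, 2), ()])
        model = RakelClassifier(L=2, k=2, m=1)
        model.n_features_ = 1
        model.lp_models_ = [
            _LPModel(
                subset=frozenset({1, 2}),
                mapping=mapping,
                estimator=_ProbStub([[0.7, 0.2, 0.1]], [0, 1, 2]),
            )
        ]
        scores = model.predict_scores_soft(np.zeros((1, 1)))
        np.testing.assert_allclose(scores[0], [0.9, 0.2])

    def test_deterministic_base_soft_equals_hard(self, separable_corpus, rf_small):
        # a constant-probability (all mass on one class) base makes soft == hard
        X, Y = _separable_xy(separable_corpus)
        model = RakelClassifier(L=7, k=7, m=1, base=rf_small, seed=0).fit(X[:20], [{1}] * 20)
        np.testing.assert_allclose(
            model.predict_scores_soft(X[:5]), model.predict_scores(X[:5])
        )

    def test_soft_scores_within_unit_interval(self, noisy_corpus, rf_small):
        X, Y = _separable_xy(noisy_corpus)
        model = RakelClassifier(L=7, k=3, m=10, base=rf_small, seed=4).fit(X, Y)
        s = model.predict_scores_soft(X)
        assert (s >= 0).all() and (s <= 1 + 1e-12).all()

    def test_probability_free_base_falls_back_with_warning(self, separable_corpus):
        X, Y = _separable_xy(separable_corpus)
        svm = BaseClassifierSpec("svm", {"C": 1.0, "kernel": "rbf", "gamma": 0.5})
        model = RakelClassifier(L=7, k=7, m=2, base=svm, seed=0).fit(X, Y)
        with pytest.warns(UserWarning, match="hard-vote"):
            s = model.predict_scores_soft(X[:10])
        np.testing.assert_array_equal(s, model.predict_scores(X[:10]))


class TestKernels:
    def test_puk_kernel_unit_diagonal(self):
        X = np.random.default_rng(1).random((6, 4))
        K = puk_kernel(X, X)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1 + 1e-12).all()

    def test_normalized_poly_unit_diagonal(self):
        X = np.random.default_rng(2).random((6, 4))
        K = normalized_poly_kernel(X, X, degree=2.0)
        np.testing.assert_allclose(np.diag(K), 1.0)

    @pytest.mark.parametrize(
        "spec",
        [
            BaseClassifierSpec("svm", {"C": 1.0, "kernel": "polynomial", "e": 2}),
            BaseClassifierSpec("svm", {"C": 1.0, "kernel": "normalized_polynomial", "e": 2}),
            BaseClassifierSpec("svm", {"C": 1.0, "kernel": "puk"}),
            BaseClassifierSpec("svm", {"C": 1.0, "kernel": "rbf", "gamma": 1.0}),
        ],
        ids=["poly", "normpoly", "puk", "rbf"],
    )
    def test_svm_kernels_fit_and_predict(self, separable_corpus, spec):
        X, Y = _separable_xy(separable_corpus)
        model = RakelClassifier(L=7, k=7, m=1, base=spec, seed=0).fit(X, Y)
        pred = model.predict(X)
        assert all(len(p) >= 1 for p in pred)
        exact = np.mean([p == y for p, y in zip(pred, Y)])
        assert exact > 0.8  # exclusive-signal corpus is nearly separable


def test_save_load_roundtrip(tmp_path, separable_corpus, rf_small):
    ds, _ = separable_corpus
    prof = build_profile(ds)
    X = encode_batch(ds, prof)
    Y = [ds.labels.labels(p) for p in ds.ids]
    model = RakelClassifier(L=7, k=3, m=5, base=rf_small, seed=6).fit(X, Y)
    model.save(tmp_path / "bundle")
    loaded = RakelClassifier.load(tmp_path / "bundle")
    assert loaded.predict(X) == model.predict(X)
    np.testing.assert_array_equal(loaded.predict_scores(X), model.predict_scores(X))
    assert loaded.labelsets_.subsets == model.labelsets_.subsets
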