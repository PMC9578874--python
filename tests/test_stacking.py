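"""The two-layer stacking ensemble and the feature-subset baselines."""

import numpy as np
import pytest

from fatiguekit.errors import InvalidArgumentError, InvalidDataError, InvalidSpecError
from fatiguekit.stacking import (
    BaseLearnerSpec,
    DEFAULT_FEATURE_SUBSETS,
    FVStackingModel,
    _Standardizer,
    baseline_compare,
    fit_base,
)


class TestBaseLearnerSpec:
    def test_modalities_inferred(self):
        assert BaseLearnerSpec("lr").modality == "facial"
        assert BaseLearnerSpec("lstm").modality == "voice"

    def test_modality_mismatch_rejected(self):
        with pytest.raises(InvalidSpecError):
            BaseLearnerSpec("lr", modality="voice")
        with pytest.raises(InvalidSpecError):
            BaseLearnerSpec("cnn", modality="facial")

    def test_unknown_learner_rejected(self):
        with pytest.raises(InvalidSpecError):
            BaseLearnerSpec("xgboost")


class TestFitBase:
    def test_linear_svm_separable_toy(self):
        x = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1],
                      [0.1, 0, 0, 0, 0], [0.9, 1, 1, 1, 1]])
        y = np.array([0, 1, 0, 1])
        learner = fit_base(BaseLearnerSpec("linear_svm"), x, None, y)
        preds = (learner.predict_proba(x) >= 0.5).astype(int)
        assert np.array_equal(preds, y)

    def test_cart_memorizes_small_sample(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 5))
        y = np.array([0, 1, 1, 0])
        learner = fit_base(BaseLearnerSpec("cart"), x, None, y)
        assert np.array_equal((learner.predict_proba(x) >= 0.5).astype(int), y)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidDataError):
            fit_base(BaseLearnerSpec("lr"), np.random.rand(4, 5), None, np.zeros(4))

    def test_voice_learner_needs_voice_input(self):
        with pytest.raises(InvalidSpecError):
            fit_base(BaseLearnerSpec("cnn"), np.random.rand(4, 5), None,
                     np.array([0, 1, 0, 1]))

    def test_voice_learners_fit_separable_mfcc(self, small_corpus):
        scaler = _Standardizer.fit(small_corpus["voice"], axis=(0, 2))
        v = scaler.transform(small_corpus["voice"]).astype(np.float32)
        y = small_corpus["labels"]
        for name in ("lstm", "cnn"):
            learner = fit_base(BaseLearnerSpec(name), None, v, y, seed=0)
            acc = np.mean((learner.predict_proba(v) >= 0.5) == y)
            assert acc > 0.8, f"{name} failed to fit separable audio classes"


class TestFitStacking:
    def test_protocol_bookkeeping_and_dimensions(self, small_corpus):
        model = FVStackingModel(small_corpus["facial"], small_corpus["voice"],
                                small_corpus["labels"], clip_ids=small_corpus["ids"])
        results = model.fit(k_folds=4, seed=0)
        assert results.verify_no_leakage()
        assert results.oof_probs.shape == (40, 5)
        assert not np.isnan(results.oof_probs).any()
        assert results.meta_coefficients.shape == (5,)
        probs = results.predict_proba(small_corpus["facial"], small_corpus["voice"])
        assert np.all((probs >= 0) & (probs <= 1))
        assert "FV-Stacking" in results.summary()

    def test_seed_determinism(self, small_corpus):
        model = FVStackingModel(small_corpus["facial"], small_corpus["voice"],
                                small_corpus["labels"])
        a = model.fit(k_folds=4, seed=3)
        b = model.fit(k_folds=4, seed=3)
        assert np.array_equal(a.meta_coefficients, b.meta_coefficients)
        pa = a.predict_proba(small_corpus["facial"][:5], small_corpus["voice"][:5])
        pb = b.predict_proba(small_corpus["facial"][:5], small_corpus["voice"][:5])
        assert np.array_equal(pa, pb)

    def test_duplication_with_same_folds_is_protocol_invariant(self, small_corpus):
        # Duplicating every sample while keeping the fold pattern leaves each
        # fold's training set (as a multiset) unchanged, so the deterministic
        # facial learners produce bit-identical out-of-fold probabilities and
        # the fused prediction stays stable (the NN learners retrain with
        # twice the updates, so only the deterministic part is exact).
        facial, voice, labels = (small_corpus["facial"], small_corpus["voice"],
                                 small_corpus["labels"])
        folds = np.arange(40) % 4
        single = FVStackingModel(facial, voice, labels).fit(seed=0, folds=folds)
        doubled = FVStackingModel(
            np.concatenate([facial, facial]),
            np.concatenate([voice, voice]),
            np.concatenate([labels, labels]),
        ).fit(seed=0, folds=np.concatenate([folds, folds]))
        assert np.array_equal(doubled.oof_probs[:40, :3], doubled.oof_probs[40:, :3])
        p_single = single.predict_proba(facial, voice) >= 0.5
        p_doubled = doubled.predict_proba(facial, voice) >= 0.5
        assert np.mean(p_single == p_doubled) >= 0.95

    def test_too_few_samples_rejected(self, small_corpus):
        model = FVStackingModel(small_corpus["facial"], small_corpus["voice"],
                                small_corpus["labels"])
        with pytest.raises(InvalidDataError):
            model.fit(k_folds=25, seed=0)

    def test_single_class_rejected(self, small_corpus):
        with pytest.raises(InvalidDataError):
            FVStackingModel(small_corpus["facial"], small_corpus["voice"],
                            np.ones_like(small_corpus["labels"]))


@pytest.fixture(scope="module")
def fitted(small_corpus):
    return FVStackingModel(small_corpus["facial"], small_corpus["voice"],
                           small_corpus["labels"]).fit(k_folds=4, seed=0)


class TestPredict:
    def test_decision_boundary_point_scores_half(self, fitted):
        coefs = fitted.meta_coefficients
        assert coefs.sum() != 0
        t = -fitted.meta_intercept / coefs.sum()
        prob = fitted.meta_probability_from_base(np.full(5, t))[0]
        assert prob == pytest.approx(0.5, abs=1e-9)

    def test_monotone_when_meta_weights_nonnegative(self, fitted, rng):
        coefs = fitted.meta_coefficients
        assert np.all(coefs >= 0), "base learners should all help on separable data"
        base = rng.random((20, 5)) * 0.5
        lo = fitted.meta_probability_from_base(base)
        hi = fitted.meta_probability_from_base(base + 0.3)
        assert np.all(hi >= lo)

    def test_prediction_deterministic(self, fitted, small_corpus):
        p1, l1 = fitted.predict(small_corpus["facial"][:3], small_corpus["voice"][:3])
        p2, l2 = fitted.predict(small_corpus["facial"][:3], small_corpus["voice"][:3])
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)


class TestBaselines:
    def test_full_subset_lr_consistent_with_fit_base(self, small_corpus):
        facial, labels = small_corpus["facial"], small_corpus["labels"]
        train_idx = np.arange(0, 30)
        test_idx = np.arange(30, 40)
        table = baseline_compare(
            facial, labels,
            [("blinks", "abt", "abti", "perclos", "fom")],
            classifiers=("lr",), split=(train_idx, test_idx),
        )
        scaler = _Standardizer.fit(facial[train_idx], axis=0)
        learner = fit_base(BaseLearnerSpec("lr"), scaler.transform(facial[train_idx]),
                           None, labels[train_idx])
        preds = (learner.predict_proba(scaler.transform(facial[test_idx])) >= 0.5).astype(int)
        manual_acc = float(np.mean(preds == labels[test_idx]))
        assert table.iloc[0]["accuracy"] == pytest.approx(manual_acc, abs=1e-12)

    def test_empty_subset_rejected(self, small_corpus):
        with pytest.raises(InvalidArgumentError):
            baseline_compare(small_corpus["facial"], small_corpus["labels"], [()])

    def test_unknown_feature_rejected(self, small_corpus):
        with pytest.raises(InvalidArgumentError):
            baseline_compare(small_corpus["facial"], small_corpus["labels"],
                             [("perclos", "eyebrow")])

    def test_default_subsets_produce_full_metric_table(self, small_corpus):
        table = baseline_compare(small_corpus["facial"], small_corpus["labels"],
                                 DEFAULT_FEATURE_SUBSETS, seed=0)
        assert len(table) == len(DEFAULT_FEATURE_SUBSETS) * 3
        for col in ("recall", "precision", "accuracy", "f1", "auc"):
            assert table[col].between(0, 1).all()
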