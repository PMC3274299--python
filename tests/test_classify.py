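"""Kennard-Stone split, PLSDA against its least-squares oracle, ED class model."""

import warnings

import numpy as np
import pytest

from benthoscan.classify import (
    CLASS_LABELS,
    EdClassModel,
    _dummy_matrix,
    count_munida,
    ed_classify,
    ed_fit,
    kennard_stone_split,
    plsda_fit,
    plsda_predict,
    sensitivity_specificity,
)


class TestKennardStone:
    def test_extreme_pair_selected_first(self):
        """On {0,1,2,10} the most distant pair {0,10} seeds the calibration set."""
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        train, test = kennard_stone_split(X, train_fraction=0.5)
        assert set(train) == {0, 3}
        assert set(test) == {1, 2}

    def test_matches_exhaustive_pair_oracle(self, rng):
        X = rng.normal(size=(15, 3))
        train, _ = kennard_stone_split(X, 0.2)  # ceil(3) = 3 -> seed pair + 1
        d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        assert {i, j} <= set(train)

    def test_two_rows_both_in_training(self):
        train, test = kennard_stone_split(np.array([[0.0], [5.0]]), 0.7)
        assert set(train) == {0, 1} and len(test) == 0

    def test_duplicate_rows_tie_break_deterministic(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        train1, _ = kennard_stone_split(X, 0.5)
        train2, _ = kennard_stone_split(X, 0.5)
        assert np.array_equal(train1, train2)
        assert set(train1) == {0, 2}  # lowest indices of the tied extreme pair

    def test_shuffle_invariance_up_to_relabelling(self, rng):
        X = rng.normal(size=(12, 4))
        perm = rng.permutation(12)
        t1, _ = kennard_stone_split(X, 0.5)
        t2, _ = kennard_stone_split(X[perm], 0.5)
        sel1 = {tuple(np.round(X[i], 12)) for i in t1}
        sel2 = {tuple(np.round(X[perm][i], 12)) for i in t2}
        assert sel1 == sel2

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            kennard_stone_split(np.zeros((1, 2)))


def _two_clouds(rng, n=30, gap=10.0):
    X = np.vstack([rng.normal(size=(n, 4)), rng.normal(size=(n, 4)) + gap])
    y = np.array([CLASS_LABELS[0]] * n + [CLASS_LABELS[1]] * n)
    return X, y


class TestPlsda:
    def test_separable_clouds_fit_perfectly(self, rng):
        X, y = _two_clouds(rng)
        model, report = plsda_fit(X, y, n_lv=2, cv="none")
        assert report.correct_model_pct == 100.0
        assert report.sensitivity_pct[CLASS_LABELS[0]] == 100.0
        assert report.specificity_pct[CLASS_LABELS[0]] == 100.0

    def test_full_rank_equals_least_squares_dummy_regression(self, rng):
        """With n_lv = rank, PLS prediction is the least-squares fit of the dummies."""
        X = rng.normal(size=(40, 6))
        y = np.array([CLASS_LABELS[i % 2] for i in range(40)])
        model, _ = plsda_fit(X, y, n_lv=6, cv="none")
        _, scores = plsda_predict(model, X)
        Y = _dummy_matrix(y)
        Xc = X - X.mean(0)
        B, *_ = np.linalg.lstsq(Xc, Y - Y.mean(0), rcond=None)
        expected = Y.mean(0) + Xc @ B
        assert np.allclose(scores, expected, rtol=1e-8, atol=1e-10)

    def test_permuted_labels_give_chance_accuracy(self):
        """Random labels on many rows / few columns: training accuracy near 50%."""
        rng = np.random.default_rng(2024)
        accs = []
        for _ in range(20):
            X = rng.normal(size=(200, 5))
            y = np.array([CLASS_LABELS[0]] * 100 + [CLASS_LABELS[1]] * 100)
            rng.shuffle(y)
            _, report = plsda_fit(X, y, n_lv=3, cv="none")
            accs.append(report.correct_model_pct)
        assert abs(np.mean(accs) - 50.0) <= 10.0

    def test_predicted_dummy_pair_sums_to_one(self, rng):
        X, y = _two_clouds(rng)
        model, _ = plsda_fit(X, y, n_lv=3, cv="none")
        _, scores = plsda_predict(model, rng.normal(size=(10, 4)))
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_mean_row_predicts_dummy_means(self, rng):
        X, y = _two_clouds(rng, n=20)
        model, _ = plsda_fit(X, y, n_lv=2, cv="none")
        _, scores = plsda_predict(model, X.mean(0, keepdims=True))
        assert np.allclose(scores[0], _dummy_matrix(y).mean(0))

    def test_duplicated_row_duplicates_prediction(self, rng):
        X, y = _two_clouds(rng, n=10)
        model, _ = plsda_fit(X, y, n_lv=2, cv="none")
        row = X[3:4]
        _, s1 = plsda_predict(model, row)
        _, s2 = plsda_predict(model, np.vstack([row, row]))
        assert np.array_equal(s2[0], s2[1]) and np.array_equal(s1[0], s2[0])

    def test_training_rows_reproduce_fitted_scores(self, rng):
        X, y = _two_clouds(rng, n=15)
        model, _ = plsda_fit(X, y, n_lv=2, cv="none")
        _, s1 = plsda_predict(model, X)
        _, s2 = plsda_predict(model, X)
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            plsda_fit(X, [CLASS_LABELS[0]] * 10)

    def test_excess_latent_vectors_truncated_with_warning(self, rng):
        X, y = _two_clouds(rng, n=5)
        with pytest.warns(UserWarning, match="rank"):
            model, _ = plsda_fit(X, y, n_lv=50, cv="none")
        assert model.n_lv <= 9

    def test_column_mismatch_rejected(self, rng):
        X, y = _two_clouds(rng)
        model, _ = plsda_fit(X, y, n_lv=2, cv="none")
        with pytest.raises(ValueError):
            plsda_predict(model, np.zeros((2, 7)))

    def test_rmsecv_loo_reported(self, rng):
        X, y = _two_clouds(rng, n=10)
        _, report = plsda_fit(X, y, n_lv=2, cv="loo")
        assert report.rmsecv is not None and report.rmsecv > 0


class TestSensitivitySpecificity:
    def test_known_confusion_counts(self):
        """TP=8 FN=2 TN=5 FP=5 gives sensitivity 80%, specificity 50%."""
        y_true = np.array([CLASS_LABELS[0]] * 10 + [CLASS_LABELS[1]] * 10)
        y_pred = np.array(
            [CLASS_LABELS[0]] * 8 + [CLASS_LABELS[1]] * 2  # 8 TP, 2 FN
            + [CLASS_LABELS[0]] * 5 + [CLASS_LABELS[1]] * 5  # 5 FP, 5 TN
        )
        sens, spec = sensitivity_specificity(y_true, y_pred)
        assert sens[CLASS_LABELS[0]] == 80.0
        assert spec[CLASS_LABELS[0]] == 50.0


class TestEdClassModel:
    def _model(self):
        return EdClassModel(
            class_centroid_rgb=np.array([100.0, 50.0, 40.0]),
            class_centroid_fd=np.zeros(128),
            threshold_rgb=10.0,
            threshold_fd=1.0,
        )

    def test_object_at_centroids_belongs(self):
        m = self._model()
        assert ed_classify(m, m.class_centroid_rgb, m.class_centroid_fd) == CLASS_LABELS[0]

    def test_rgb_distance_just_above_threshold_rejected(self):
        m = self._model()
        rgbv = m.class_centroid_rgb + np.array([10.001, 0, 0])
        assert ed_classify(m, rgbv, m.class_centroid_fd) == CLASS_LABELS[1]

    def test_distances_match_direct_formula(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 128))
            direct = np.sqrt(((a - b) ** 2).sum())
            m = EdClassModel(np.zeros(3), b, threshold_rgb=1e9, threshold_fd=direct * (1 + 1e-9))
            assert ed_classify(m, np.zeros(3), a) == CLASS_LABELS[0]
            m_tight = EdClassModel(np.zeros(3), b, 1e9, direct * (1 - 1e-9))
            assert ed_classify(m_tight, np.zeros(3), a) == CLASS_LABELS[1]

    def test_fit_thresholds_cover_training_quantile(self, rng):
        rgb = rng.normal(size=(100, 3))
        fd = rng.normal(size=(100, 128))
        m = ed_fit(rgb, fd, threshold_percentile=95)
        inside = [
            ed_classify(m, r, f) == CLASS_LABELS[0] for r, f in zip(rgb, fd)
        ]
        assert 0.85 <= np.mean(inside) <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ed_classify(self._model(), np.zeros(4), np.zeros(128))


class TestCountMunida:
    def test_no_objects_counts_zero(self):
        assert count_munida("fd_plsda", objects=[], plsda=object()) == 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            count_munida("nearest_neighbour", objects=[])

    def test_sift_with_all_non_belonging_counts_zero(self, rng):
        from benthoscan.keypoints import KeypointFeature

        X, y = _two_clouds(rng, n=10)
        # train a 128-column model whose "not belonging" region is far away
        Xw = np.hstack([X, np.zeros((20, 124))])
        model, _ = plsda_fit(Xw, y, n_lv=2, cv="none")
        feats = [
            KeypointFeature(
                position=(0.0, 0.0), scale=1.0, orientation=0.0,
                descriptor=np.concatenate([np.full(4, 10.0), np.zeros(124)]),
            )
            for _ in range(9)
        ]
        assert count_munida("sift_plsda", features=feats, plsda=model) == 0
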