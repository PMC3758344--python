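"""PCA against an independent oracle; NIPALS PLS-DA and leakage-free LOOCV."""

import numpy as np
import pandas as pd
import pytest

from kinarray import loocv, pca_fit, plsda_fit, plsda_predict
from kinarray.pipeline import braf_groups
from kinarray import compute_lfc


class TestPca:
    def test_rank_one_data_explained_by_pc1(self):
        x = np.array([[1.0], [2.0], [4.0], [7.0]])
        X = np.hstack([x, 2 * x])
        res = pca_fit(X, n_components=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_conservation_at_full_rank(self, rng):
        X = rng.normal(size=(8, 5))
        res = pca_fit(X, n_components=5)
        total_in = ((X - X.mean(0)) ** 2).sum()
        total_scores = (res.scores**2).sum()
        assert total_scores == pytest.approx(total_in, rel=1e-12)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        # loadings orthonormal
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(5), atol=1e-10
        )

    def test_explained_fractions_non_increasing(self, rng):
        res = pca_fit(rng.normal(size=(10, 20)), n_components=5)
        assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()

    def test_matches_sklearn_oracle_up_to_sign(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(10, 20))
        res = pca_fit(X, n_components=5)
        ref = sklearn_pca(n_components=5, svd_solver="full").fit(X)
        for k in range(5):
            sign = np.sign(res.loadings[:, k] @ ref.components_[k])
            np.testing.assert_allclose(
                res.loadings[:, k], sign * ref.components_[k], atol=1e-8
            )
            np.testing.assert_allclose(
                res.scores[:, k], sign * ref.transform(X)[:, k], atol=1e-8
            )
        np.testing.assert_allclose(
            res.explained_variance_fraction,
            ref.explained_variance_ratio_,
            atol=1e-10,
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.ones((1, 4)), 1)


class TestPlsdaFit:
    def test_separable_training_scores_sign_split(self):
        X = np.vstack([np.full((4, 3), -2.0), np.full((4, 3), 2.0)])
        X[:, 1:] = 0.0
        X += np.arange(8)[:, None] * 1e-3  # break exact ties
        y = ["wild_type"] * 4 + ["V600E"] * 4
        m = plsda_fit(X, y, n_components=1, classes=("wild_type", "V600E"))
        assert (m.training_scores[:4] < 0).all()
        assert (m.training_scores[4:] > 0).all()

    def test_one_component_is_mean_difference_direction(self, rng):
        X = rng.normal(size=(10, 2))
        y = ["a"] * 4 + ["b"] * 6
        m = plsda_fit(X, y, n_components=1, classes=("a", "b"))
        Xc = X - X.mean(0)
        diff = Xc[4:].mean(0) - Xc[:4].mean(0)
        cos = (m.regression_vector @ diff) / (
            np.linalg.norm(m.regression_vector) * np.linalg.norm(diff)
        )
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_pls1_reference(self, rng):
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        for _ in range(5):
            X = rng.normal(size=(10, 15))
            y = np.array([-1.0] * 5 + [1.0] * 5)
            m = plsda_fit(X, y, n_components=2)
            ref = PLSRegression(n_components=2, scale=False).fit(X, y)
            ours = plsda_predict(m, X) + m.y_mean
            theirs = ref.predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            plsda_fit(np.random.default_rng(0).normal(size=(4, 3)), ["a"] * 4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            plsda_fit(np.ones((4, 3)), ["a", "a", "b", "b"])


class TestPlsdaPredict:
    @pytest.fixture
    def toy_model(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(-1, 0.1, size=(5, 4)), rng.normal(1, 0.1, size=(5, 4))]
        )
        y = ["wild_type"] * 5 + ["V600E"] * 5
        return X, plsda_fit(X, y, n_components=2, classes=("wild_type", "V600E"))

    def test_class_mean_scores_positive(self, toy_model):
        X, m = toy_model
        assert plsda_predict(m, X[5:].mean(0)) > 0
        assert plsda_predict(m, X[:5].mean(0)) < 0

    def test_overall_mean_scores_zero(self, toy_model):
        X, m = toy_model
        assert plsda_predict(m, X.mean(0)) == pytest.approx(0.0, abs=1e-10)

    def test_zero_score_called_wild_type(self, toy_model):
        _, m = toy_model
        assert m.classify(0.0) == "wild_type"
        assert m.classify(1e-9) == "V600E"

    def test_length_mismatch(self, toy_model):
        _, m = toy_model
        with pytest.raises(ValueError):
            plsda_predict(m, np.zeros(7))


class TestLoocv:
    def test_no_leakage_from_held_out_sample(self, rng):
        # changing only the held-out row must not change its fold's model,
        # hence its prediction score changes only via its own features
        X = rng.normal(size=(8, 5))
        y = ["a"] * 4 + ["b"] * 4
        base = loocv(X, y, n_components=2)
        X2 = X.copy()
        X2[0] += 100.0  # corrupt the held-out sample for fold 0
        alt = loocv(X2, y, n_components=2)
        # folds 1..7 saw a different training row, so only fold 0's model
        # is provably identical: its score must move exactly with the
        # regression vector of the unchanged model
        m0 = plsda_fit(X[1:], y[1:], n_components=2, classes=("a", "b"))
        assert alt.prediction_scores[0] == pytest.approx(
            plsda_predict(m0, X2[0]), abs=1e-10
        )
        assert base.prediction_scores[0] == pytest.approx(
            plsda_predict(m0, X[0]), abs=1e-10
        )

    def test_separated_synthetic_classified_perfectly(self, default_run):
        exp, _ = default_run
        prof = compute_lfc(exp, "vemurafenib")
        groups = braf_groups(exp.annotations, prof.sample_ids)
        labelled = groups["wild_type"] + groups["V600E"]
        y = ["wild_type"] * len(groups["wild_type"]) + ["V600E"] * len(
            groups["V600E"]
        )
        cv = loocv(prof.lfc.loc[labelled], y, n_components=2,
                   classes=("wild_type", "V600E"))
        assert cv.overall_accuracy == 1.0
        assert cv.invalid_folds == []
        assert len(cv.sample_ids) == 25  # the unknown-BRAF tumor is excluded

    def test_permuted_labels_hover_at_chance(self, rng):
        X = rng.normal(size=(20, 30))
        y = np.array(["a"] * 8 + ["b"] * 12)
        accs = []
        for _ in range(30):
            accs.append(loocv(X, rng.permutation(y), n_components=2).overall_accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_tiny_balanced_duplicated_exemplars(self):
        X = np.array([[0.0, 1.0], [0.1, 1.1], [5.0, -1.0], [5.1, -0.9]])
        cv = loocv(X, ["a", "a", "b", "b"], n_components=1)
        assert cv.overall_accuracy == 1.0

    def test_confusion_counts_sum(self, rng):
        X = rng.normal(size=(10, 6))
        y = ["a"] * 5 + ["b"] * 5
        cv = loocv(X, y)
        assert sum(cv.confusion.values()) == 10

    def test_frame_matches_scores(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(8, 4)), index=[f"s{i}" for i in range(8)]
        )
        cv = loocv(X, ["a"] * 4 + ["b"] * 4)
        frame = cv.frame()
        assert list(frame["sample_id"]) == list(X.index)
        np.testing.assert_allclose(
            frame["prediction_score"], cv.prediction_scores
        )
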