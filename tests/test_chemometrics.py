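"""Latent-model oracles: PLS vs least squares/sklearn, VIP identity, Q2,
orthogonal filtering, permutation behavior, classification metrics."""

import numpy as np
import pandas as pd
import pytest

from voctrace import chemometrics as cm


def three_clouds(rng, n=10, sep=4.0, p=6):
    X = np.vstack(
        [rng.normal(sep * k, 1.0, (n, p)) * (1 + 0.1 * k) for k in range(3)]
    )
    y = np.repeat(["a", "b", "c"], n)
    return X, y


class TestPca:
    def test_rank_one_data(self, rng):
        v = rng.normal(size=8)
        X = np.outer(rng.normal(size=20), v)
        _, frac = cm.pca(X, 1)
        assert frac[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_variance(self, rng):
        X = rng.normal(size=(4000, 2))
        _, frac = cm.pca(X, 2)
        assert abs(frac[0] - 0.5) < 0.05 and abs(frac[1] - 0.5) < 0.05

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(15, 6))
        model, _ = cm.pca(X, 6)
        rec = model.inverse_transform(model.transform(X))
        assert np.abs(rec - X).max() < 1e-8

    def test_rank_overflow_truncates_with_warning(self, rng):
        v = rng.normal(size=5)
        X = np.outer(rng.normal(size=10), v)
        with pytest.warns(UserWarning, match="rank"):
            _, frac = cm.pca(X, 4)
        assert len(frac) == 1


class TestPlsda:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(8, 1, (10, 4))])
        y = np.repeat(["a", "b"], 10)
        model = cm.plsda(X, y, A=1)
        assert (model.predict(X) == y).all()

    def test_full_rank_equals_least_squares(self, rng):
        X, y = three_clouds(rng, n=8)
        model = cm.plsda(X, y, A=6)
        Y, _ = cm.one_hot(y)
        Xd = np.c_[np.ones(X.shape[0]), X]
        beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        assert np.abs(model.predict_continuous(X) - Xd @ beta).max() < 1e-6

    def test_matches_sklearn_pls2(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, y = three_clouds(rng)
        Y, _ = cm.one_hot(y)
        model = cm.plsda(X, y, A=3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, Y)
        assert np.abs(model.predict_continuous(X) - sk.predict(X)).max() < 1e-3

    def test_permuted_labels_reduce_r2y(self, rng):
        X, y = three_clouds(rng)
        base = cm.plsda(X, y, A=2).r2y
        worse = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            perm = cm.plsda(X, r.permutation(y), A=2).r2y
            worse += perm < base
        assert worse == 20

    def test_zero_components_predicts_majority(self, rng):
        X = rng.normal(size=(9, 4))
        y = np.array(["a"] * 5 + ["b"] * 4)
        model = cm.plsda(X, y, A=0)
        assert (model.predict(X) == "a").all()

    def test_score_orthogonality(self, rng):
        X, y = three_clouds(rng)
        T = cm.plsda(X, y, A=3).T
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


class TestOplsda:
    def test_zero_ortho_equals_plsda(self, rng):
        X, y = three_clouds(rng)
        m1 = cm.plsda(X, y, A=2)
        m2, _ = cm.oplsda(X, y, n_ortho=0, A=2)
        assert (m1.predict(X) == m2.predict(X)).all()
        assert np.abs(m1.predict_continuous(X) - m2.predict_continuous(X)).max() < 1e-10

    def test_structured_orthogonal_noise_helps(self, rng):
        """Removing y-orthogonal structure should not hurt Q2 when such
        structure dominates X."""
        n, p = 45, 30
        y = np.repeat(["a", "b", "c"], 15)
        Y, _ = cm.one_hot(y)
        signal_dir = rng.normal(size=(3, p))
        noise_dir = rng.normal(size=p)
        X = Y @ signal_dir + 8.0 * rng.normal(size=(n, 1)) * noise_dir + 0.3 * rng.normal(size=(n, p))
        q2_0, _ = cm.cross_val_q2(X, y, A=2, n_ortho=0)
        q2_1, _ = cm.cross_val_q2(X, y, A=2, n_ortho=1)
        assert q2_1 >= q2_0

    def test_predictive_and_orthogonal_scores_uncorrelated(self, rng):
        X, y = three_clouds(rng, p=10)
        model, _ = cm.oplsda(X, y, n_ortho=2, A=2)
        for a in range(model.A):
            for o in range(model.n_ortho):
                r = np.corrcoef(model.T[:, a], model.T_o[:, o])[0, 1]
                assert abs(r) < 1e-6

    def test_q2_never_exceeds_r2y(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = three_clouds(r, sep=1.0)
            model, metrics = cm.oplsda(X, y, n_ortho=1, A=2)
            assert metrics.q2 <= metrics.r2y + 1e-9

    def test_too_many_ortho_components_rejected(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=5))
        y = np.repeat(["a", "b"], 6)
        with pytest.raises(ValueError):
            cm.oplsda(X, y, n_ortho=4, A=1)

    def test_separated_spectra_reach_benchmark(self, deriv_features):
        """Well-separated 3-class spectra: R2Y > 0.9 and Q2 > 0.7."""
        X, y = deriv_features
        model, metrics = cm.oplsda(X, y)
        assert metrics.r2y > 0.9
        assert metrics.q2 > 0.7
        assert 0 <= metrics.r2x <= 1


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        X, y = three_clouds(rng, p=9)
        for A in (1, 2, 3):
            v = cm.vip(cm.plsda(X, y, A=A))
            assert np.mean(np.asarray(v) ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_single_component_reduction(self, rng):
        X, y = three_clouds(rng, p=7)
        model = cm.plsda(X, y, A=1)
        w = model.W[:, 0]
        expected = np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
        assert np.allclose(np.asarray(cm.vip(model)), expected)

    def test_informative_variable_has_max_vip(self, rng):
        n = 40
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 12))
        X[:, 5] += 3.0 * (y == "a")
        v = np.asarray(cm.vip(cm.plsda(X, y, A=1)))
        assert v.argmax() == 5 and v[5] > 1

    def test_dataframe_input_yields_named_series(self, rng):
        X, y = three_clouds(rng, p=4)
        df = pd.DataFrame(X, columns=list("wxyz"))
        v = cm.vip(cm.plsda(df, y, A=2))
        assert isinstance(v, pd.Series) and list(v.index) == list("wxyz")


class TestPermutationTest:
    def test_fixed_seed_reproducible(self, rng):
        X, y = three_clouds(rng, n=7)
        a = cm.permutation_test(X, y, n_perm=25, seed=3)
        b = cm.permutation_test(X, y, n_perm=25, seed=3)
        assert np.array_equal(a.q2_perm, b.q2_perm)
        assert a.valid == b.valid

    def test_separable_classes_validate(self, rng):
        X, y = three_clouds(rng, n=8)
        rec = cm.permutation_test(X, y, n_perm=30, seed=0)
        assert rec.valid
        assert rec.q2 > max(rec.q2_perm)

    def test_pure_noise_fails_validation(self):
        invalid = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(24, 10))
            y = np.repeat(["a", "b", "c"], 8)
            rec = cm.permutation_test(X, y, n_perm=25, seed=seed)
            invalid += not rec.valid
        assert invalid >= 9

    def test_too_few_permutations_rejected(self, rng):
        X, y = three_clouds(rng, n=4)
        with pytest.raises(ValueError):
            cm.permutation_test(X, y, n_perm=5)


class TestClassMetrics:
    def test_perfect_prediction(self):
        y = np.repeat(["a", "b", "c"], 4)
        m = cm.class_metrics(y, y)
        assert m.accuracy == 1.0 and m.f1 == pytest.approx(1.0)

    def test_single_class_prediction_on_balanced_three_classes(self):
        y = np.repeat(["a", "b", "c"], 5)
        m = cm.class_metrics(y, np.repeat("a", 15))
        assert m.accuracy == pytest.approx(1 / 3)

    def test_hand_confusion_matrix(self):
        y_true = ["a", "a", "a", "b", "b", "b"]
        y_pred = ["a", "a", "b", "b", "b", "b"]
        m = cm.class_metrics(y_true, y_pred)
        assert np.array_equal(m.confusion.to_numpy(), [[2, 1], [0, 3]])
        assert m.accuracy == pytest.approx(5 / 6)
        assert m.precision == pytest.approx((1.0 + 0.75) / 2)

    def test_unseen_predicted_label_warns(self):
        with pytest.warns(UserWarning, match="unseen"):
            m = cm.class_metrics(["a", "a"], ["a", "z"])
        assert "z" in m.confusion.columns
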