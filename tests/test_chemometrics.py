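import numpy as np
import pytest

from hsichem.chemometrics import (
    SplitSpec,
    compute_metrics,
    cross_validate,
    evaluate_model,
    fit_pcr,
    fit_plsr,
    kennard_stone,
    model_comparison_table,
    predict,
    select_n_components,
    split_calibration_prediction,
)
from hsichem.preprocess import PreprocessSpec


def ols_predict(X, y, X_new):
    """Normal-equations oracle on centered data."""
    xm, ym = X.mean(axis=0), y.mean()
    b, *_ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
    return ym + (X_new - xm) @ b


def random_problem(rng, n=20, p=5):
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return X, y


class TestSplit:
    def test_fraction_floor_rule(self, rng):
        X = rng.standard_normal((96, 4))
        cal, pred = split_calibration_prediction(X, SplitSpec(cal_fraction=0.75))
        assert len(cal) == 72 and len(pred) == 24

    def test_disjoint_exhaustive(self, rng):
        X = rng.standard_normal((30, 3))
        cal, pred = split_calibration_prediction(X, SplitSpec(method="random", seed=3))
        assert len(np.intersect1d(cal, pred)) == 0
        assert sorted([*cal, *pred]) == list(range(30))

    def test_kennard_stone_collinear_picks_extremes_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        sel = kennard_stone(X, 2)
        assert set(sel) == {0, 2}

    def test_kennard_stone_maxmin_oracle(self, rng):
        # brute-force check of the greedy max-min rule on a tiny instance
        X = rng.standard_normal((8, 2))
        sel = kennard_stone(X, 5)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        chosen = {i, j}
        while len(chosen) < 5:
            rest = [k for k in range(8) if k not in chosen]
            nxt = max(rest, key=lambda k: min(d[k, c] for c in chosen))
            chosen.add(nxt)
        assert set(sel) == chosen

    def test_determinism(self, rng):
        X = rng.standard_normal((20, 3))
        s = SplitSpec(method="random", seed=11)
        a = split_calibration_prediction(X, s)
        b = split_calibration_prediction(X, s)
        np.testing.assert_array_equal(a[0], b[0])

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            split_calibration_prediction(rng.standard_normal((3, 2)), SplitSpec())


class TestPlsr:
    def test_exact_fit_noiseless(self, rng):
        X = rng.standard_normal((25, 6))
        beta = rng.standard_normal(6)
        y = X @ beta + 2.0
        model = fit_plsr(X, y, 6)
        r2, rmse = compute_metrics(y, predict(model, X))
        assert r2 == pytest.approx(1.0, abs=1e-8)
        assert rmse < 1e-7

    def test_rank_one_equals_univariate_regression(self, rng):
        t = rng.standard_normal(15)
        direction = rng.standard_normal(4)
        X = np.outer(t, direction)
        y = 3.0 * t + rng.standard_normal(15) * 0.1
        model = fit_plsr(X, y, 1)
        # closed-form regression of y on the single centered score
        score = (X - X.mean(axis=0)) @ direction / np.linalg.norm(direction)
        slope = score @ (y - y.mean()) / (score @ score)
        expected = y.mean() + slope * score
        np.testing.assert_allclose(predict(model, X), expected, atol=1e-8)

    def test_full_rank_equals_ols_20_instances(self, rng):
        for _ in range(20):
            X, y = random_problem(rng)
            model = fit_plsr(X, y, 5)
            np.testing.assert_allclose(predict(model, X), ols_predict(X, y, X), atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X, y = random_problem(rng, n=30, p=10)
        model = fit_plsr(X, y, 6)
        T = model.scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()

    def test_zero_variance_y_raises(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(X, np.full(10, 2.0), 2)

    def test_training_fit_reproducible_from_stored_coefficients(self, rng):
        X, y = random_problem(rng)
        model = fit_plsr(X, y, 3)
        manual = model.y_mean + (X - model.x_mean) @ model.coefficients
        np.testing.assert_allclose(predict(model, X), manual, atol=1e-12)


class TestPcr:
    def test_full_rank_equals_ols(self, rng):
        for _ in range(20):
            X, y = random_problem(rng)
            model = fit_pcr(X, y, 5)
            np.testing.assert_allclose(predict(model, X), ols_predict(X, y, X), atol=1e-8)

    def test_k1_matches_eigendecomposition_oracle(self, rng):
        base = rng.standard_normal((40, 6))
        base[:, 0] *= 10.0  # dominant direction
        Xc = base - base.mean(axis=0)
        y = rng.standard_normal(40)
        # oracle: regress y on the first eigenvector score of the covariance
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        v1 = evecs[:, -1]
        score = Xc @ v1
        slope = score @ (y - y.mean()) / (score @ score)
        expected = y.mean() + slope * score
        model = fit_pcr(base, y, 1)
        np.testing.assert_allclose(predict(model, base), expected, atol=1e-8)

    def test_component_variance_non_increasing(self, rng):
        X, y = random_problem(rng, n=30, p=8)
        model = fit_pcr(X, y, 6)
        variances = (model.scores**2).sum(axis=0)
        assert np.all(np.diff(variances) <= 1e-10)


class TestPlsVsPcr:
    def test_pls_ssres_never_exceeds_pcr_at_equal_k(self, rng):
        for _ in range(20):
            X, y = random_problem(rng, n=25, p=10)
            for k in (1, 2, 3):
                ss_pls = np.sum((y - predict(fit_plsr(X, y, k), X)) ** 2)
                ss_pcr = np.sum((y - predict(fit_pcr(X, y, k), X)) ** 2)
                assert ss_pls <= ss_pcr + 1e-10

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(rng, n=30, p=12)
        model = fit_plsr(X, y, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            predict(model, X), ref.predict(X).ravel(), atol=1e-8
        )


class TestPredict:
    def test_x_mean_maps_to_y_mean(self, rng):
        X, y = random_problem(rng)
        model = fit_plsr(X, y, 3)
        assert predict(model, model.x_mean) == pytest.approx(model.y_mean, abs=1e-12)

    def test_single_equals_batch_row(self, rng):
        X, y = random_problem(rng)
        model = fit_plsr(X, y, 3)
        batch = predict(model, X)
        assert predict(model, X[7]) == pytest.approx(batch[7], abs=1e-12)

    def test_band_mismatch_raises(self, rng):
        X, y = random_problem(rng)
        model = fit_plsr(X, y, 2)
        with pytest.raises(ValueError, match="bands"):
            predict(model, np.ones((3, 9)))


class TestCrossValidation:
    def test_loo_matches_explicit_refit_loop(self, rng):
        X, y = random_problem(rng, n=5, p=3)
        spec = SplitSpec(leave_one_out=True, seed=4)
        rcv2, rmsecv = cross_validate(X, y, "PLSR", 2, spec)
        # oracle: refit by hand for each left-out sample
        preds = np.empty(5)
        from hsichem.chemometrics import _fold_indices

        for test_idx in _fold_indices(5, 5, 4):
            train = np.setdiff1d(np.arange(5), test_idx)
            m = fit_plsr(X[train], y[train], 2)
            preds[test_idx] = predict(m, X[test_idx])
        exp_r2, exp_rmse = compute_metrics(y, preds)
        assert rcv2 == pytest.approx(exp_r2, abs=1e-10)
        assert rmsecv == pytest.approx(exp_rmse, abs=1e-10)

    def test_noiseless_linear_gives_unit_rcv2(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ rng.standard_normal(5) + 1.0
        rcv2, _ = cross_validate(X, y, "PLSR", 5, SplitSpec(cv_folds=5, seed=0))
        assert rcv2 == pytest.approx(1.0, abs=1e-8)

    def test_deterministic_given_seed(self, rng):
        X, y = random_problem(rng, n=30, p=6)
        a = cross_validate(X, y, "PCR", 3, SplitSpec(cv_folds=5, seed=9))
        b = cross_validate(X, y, "PCR", 3, SplitSpec(cv_folds=5, seed=9))
        assert a == b


class TestComponentSelection:
    def test_single_candidate(self, rng):
        X, y = random_problem(rng, n=10, p=3)
        assert select_n_components(X, y, "PLSR", max_k=1) == 1

    def test_recovers_latent_rank(self, rng):
        # 3 latent factors, 1% noise: parsimony rule should land on 3 or 4
        T = rng.standard_normal((60, 3))
        P = rng.standard_normal((3, 50))
        X = T @ P + 0.01 * rng.standard_normal((60, 50))
        y = T @ np.array([1.0, -2.0, 0.5]) + 0.01 * rng.standard_normal(60)
        k = select_n_components(X, y, "PLSR", max_k=10, spec=SplitSpec(cv_folds=5, seed=2))
        assert k in (3, 4)

    def test_parsimony_rule_first_within_tolerance(self, rng, monkeypatch):
        # force a known RMSECV profile: decreasing then flat
        profile = {1: 1.0, 2: 0.5, 3: 0.101, 4: 0.1, 5: 0.1}
        import hsichem.chemometrics as cm

        monkeypatch.setattr(cm, "cross_validate", lambda X, y, kind, k, spec: (0.0, profile[k]))
        X, y = random_problem(rng, n=10, p=5)
        assert cm.select_n_components(X, y, "PLSR", max_k=5) == 3  # 0.101 <= 0.1 * 1.02


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert compute_metrics(y, y) == (1.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = compute_metrics(y, np.full(3, 2.0))
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        r2, rmse = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_constant_y_true_raises(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def dataset():
    # spectra-like: large shared baseline, small informative latent variation
    rng = np.random.default_rng(0)
    n, p = 40, 24
    latent = rng.standard_normal((n, 3))
    loadings = rng.standard_normal((3, p)) * 0.05
    baseline = 0.6 + 0.2 * np.sin(np.linspace(0, 3, p))
    X = baseline + latent @ loadings + 0.001 * rng.standard_normal((n, p))
    labels = {
        "a": latent @ np.array([1.0, 0.2, -0.3]) + 5.0,
        "b": latent @ np.array([-0.5, 1.0, 0.1]) + 2.0,
    }
    return X, labels


class TestComparisonTable:

    def test_row_count_and_layout(self, dataset):
        X, labels = dataset
        table = model_comparison_table(X, labels, split=SplitSpec(seed=1), max_k=6)
        assert len(table) == 2 * 3 * 2  # analytes x pretreatments x models
        assert set(table["preprocess"]) == {"SG", "GF", "N"}
        assert set(table["model"]) == {"PLSR", "PCR"}
        assert table.groupby("analyte")["best"].sum().eq(1).all()

    def test_deterministic(self, dataset):
        X, labels = dataset
        t1 = model_comparison_table(X, labels, split=SplitSpec(seed=1), max_k=6)
        t2 = model_comparison_table(X, labels, split=SplitSpec(seed=1), max_k=6)
        assert t1.equals(t2)

    def test_low_noise_dataset_predicts_well(self, dataset):
        X, labels = dataset
        table = model_comparison_table(X, labels, split=SplitSpec(seed=1), max_k=6)
        assert (table["RP2"] >= 0.95).all()
        assert (table["RMSEP"] <= 2.0 * table["RMSEC"] + 1e-9).all()


class TestEvaluateModel:
    def test_preprocessing_recorded_in_model(self, rng):
        X = rng.uniform(0.2, 0.9, (30, 32))
        y = X[:, 5] * 3.0 + rng.standard_normal(30) * 0.01
        spec = PreprocessSpec(method="GF")
        model, metrics = evaluate_model(X, y, "PLSR", spec, split=SplitSpec(seed=0), max_k=5)
        assert model.preprocess == spec
        assert metrics.rmsec >= 0 and metrics.rc2 <= 1.0
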