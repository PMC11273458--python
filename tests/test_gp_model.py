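"""GP regression: posterior correctness, evidence optimization, CV, baselines."""

import numpy as np
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from armlearn.gp_model import (
    GPConfig,
    cross_validate,
    fit_baselines,
    fit_gp,
    kernel_matrix,
    noise_sensitivity_curve,
    predict,
    _nll_and_grad,
)


def _toy(n=8, d=3, seed=0, sigma=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.sin(X[:, 0]) + 0.3 * X[:, 1] + rng.normal(0, sigma, n)
    return X, y


def dense_posterior(fit, Xs):
    """Independent dense-linear-algebra oracle via explicit matrix inverse."""
    Kn = fit.kernel(fit.X, fit.X) + (fit.config.sigma_log**2 + fit.config.jitter) * np.eye(
        fit.n_training
    )
    Kinv = np.linalg.inv(Kn)
    Ks = fit.kernel(Xs, fit.X)
    mu = fit.y_mean + Ks @ Kinv @ (fit.y - fit.y_mean)
    var = np.diag(fit.kernel(Xs, Xs)) - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mu, np.sqrt(np.maximum(var, 0.0))


@pytest.mark.parametrize("kernel", ["matern52", "matern32", "rbf", "linear"])
def test_posterior_matches_dense_oracle(kernel):
    X, y = _toy()
    fit = fit_gp(X, y, GPConfig(kernel=kernel, sigma_log=0.1, n_restarts=2))
    Xs = np.random.default_rng(1).normal(size=(6, 3))
    pred = predict(fit, Xs)
    mu, sd = dense_posterior(fit, Xs)
    assert np.abs(pred.mean - mu).max() < 1e-8
    assert np.abs(pred.std - sd).max() < 1e-8


def test_posterior_matches_sklearn_gp():
    """Cross-check against an independent GP implementation."""
    X, y = _toy(n=20)
    fit = fit_gp(X, y, GPConfig(sigma_log=0.15, n_restarts=2, jitter=0.0))
    sk = GaussianProcessRegressor(
        kernel=ConstantKernel(fit.sf2, "fixed")
        * Matern(length_scale=fit.lengthscales[0], length_scale_bounds="fixed", nu=2.5),
        alpha=0.15**2,
        optimizer=None,
        normalize_y=False,
    ).fit(X, y - fit.y_mean)
    Xs = np.random.default_rng(2).normal(size=(5, 3))
    mu, sd = sk.predict(Xs, return_std=True)
    pred = predict(fit, Xs)
    assert np.abs(pred.mean - (mu + fit.y_mean)).max() < 1e-7
    assert np.abs(pred.std - sd).max() < 1e-6


def test_analytic_gradients_match_finite_differences():
    X, y = _toy(n=15)
    for cfg in (
        GPConfig(ard=True, sigma_log=0.1),
        GPConfig(kernel="rbf", ard=True, sigma_log=0.1),
        GPConfig(kernel="matern32", sigma_log=0.1),
        GPConfig(kernel="additive_matern", sigma_log=0.1, blocks=((0, 1), (1, 2), (2, 3))),
        GPConfig(kernel="linear", sigma_log=0.1),
    ):
        n_theta = {"linear": 1}.get(cfg.kernel, (3 if cfg.ard or cfg.kernel == "additive_matern" else 1) + 1)
        theta = 0.1 + 0.05 * np.arange(n_theta)
        f0, g = _nll_and_grad(theta, X, y - y.mean(), cfg)
        num = np.zeros_like(theta)
        for i in range(len(theta)):
            t = theta.copy()
            t[i] += 1e-6
            num[i] = (_nll_and_grad(t, X, y - y.mean(), cfg)[0] - f0) / 1e-6
        assert np.abs(g - num).max() < 1e-4, cfg.kernel


def test_fit_is_deterministic_and_ascends():
    X, y = _toy(n=30)
    cfg = GPConfig(sigma_log=0.1, n_restarts=3, seed=5)
    f1 = fit_gp(X, y, cfg)
    f2 = fit_gp(X, y, cfg)
    assert f1.sf2 == f2.sf2
    assert np.array_equal(f1.lengthscales, f2.lengthscales)
    # Evidence at the optimum is at least the evidence at the default start.
    theta0 = np.array([np.log(max((y - y.mean()).var(), 1e-3)), np.log(np.sqrt(X.shape[1]))])
    nll0, _ = _nll_and_grad(theta0, X, y - y.mean(), cfg)
    assert f1.log_marginal_likelihood >= -nll0 - 1e-9


def test_noiseless_gp_interpolates_training_points():
    X, y = _toy(n=10, sigma=0.0)
    fit = fit_gp(X, y, GPConfig(sigma_log=0.0, n_restarts=2))
    pred = predict(fit, X)
    assert np.abs(pred.mean - y).max() < 1e-4
    assert pred.std.max() < 1e-3


def test_far_candidates_revert_to_prior():
    X, y = _toy(n=12)
    fit = fit_gp(X, y, GPConfig(sigma_log=0.1, n_restarts=2))
    far = np.full((1, 3), 1e4)
    pred = predict(fit, far)
    assert pred.mean[0] == pytest.approx(fit.y_mean, abs=1e-6)
    assert pred.std[0] == pytest.approx(np.sqrt(fit.sf2), rel=1e-6)


def test_matern52_gram_is_positive_semidefinite(rng):
    X = rng.normal(size=(40, 6))
    K = kernel_matrix(X, X, "matern52", 1.7, np.array([0.8]))
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


def test_adding_a_training_point_never_increases_variance(rng):
    X, y = _toy(n=12)
    grid = rng.normal(size=(30, 3))
    fit_a = fit_gp(X[:-1], y[:-1], GPConfig(sigma_log=0.1, n_restarts=1))
    cfg_b = GPConfig(sigma_log=0.1, n_restarts=1)
    # Same hyperparameters, one more conditioning point: use the dense oracle.
    from armlearn.gp_model import GPFit
    from scipy.linalg import cho_solve, cholesky

    Kn = fit_a.kernel(X, X) + (0.1**2 + fit_a.config.jitter) * np.eye(len(y))
    L = cholesky(Kn, lower=True)
    fit_b = GPFit(
        config=fit_a.config, X=X, y=y, y_mean=fit_a.y_mean, sf2=fit_a.sf2,
        lengthscales=fit_a.lengthscales, log_marginal_likelihood=0.0, L=L,
        alpha=cho_solve((L, True), y - fit_a.y_mean),
    )
    var_small = predict(fit_a, grid).std ** 2
    var_big = predict(fit_b, grid).std ** 2
    assert (var_big <= var_small + 1e-10).all()


def test_lengthscale_recovery_within_factor_two():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(100, 3))
    true_ls = 2.0
    K = kernel_matrix(X, X, "matern52", 1.0, np.array([true_ls]))
    y = rng.multivariate_normal(np.zeros(100), K + 0.05**2 * np.eye(100))
    fit = fit_gp(X, y, GPConfig(sigma_log=0.05, n_restarts=3, seed=1))
    assert true_ls / 2 <= fit.lengthscales[0] <= true_ls * 2


def test_cross_validation_partitions_by_variant(rng):
    n_var = 30
    groups = np.repeat([f"v{i}" for i in range(n_var)], 2)
    X = rng.normal(size=(60, 3))
    y = rng.normal(size=60)
    from sklearn.model_selection import GroupKFold

    seen = []
    for tr, te in GroupKFold(n_splits=5).split(X, y, groups):
        assert set(groups[tr]).isdisjoint(set(groups[te]))
        seen.extend(te.tolist())
    assert sorted(seen) == list(range(60))


def test_cv_recovers_linear_signal_and_rejects_permuted_labels():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(120, 5))
    w = rng.normal(size=5)
    y = X @ w
    groups = np.array([f"v{i}" for i in range(120)])
    cfg = GPConfig(kernel="linear", sigma_log=0.01, n_restarts=2, k_folds=5)
    cv = cross_validate(X, y, groups, cfg)
    assert cv["r2"].median() >= 0.99
    y_perm = rng.permutation(y)
    cv_perm = cross_validate(X, y_perm, groups, cfg)
    assert cv_perm["r2"].median() <= 0.05


def test_cv_rejects_too_many_folds(rng):
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    groups = [f"v{i}" for i in range(10)]
    with pytest.raises(ValueError, match="15"):
        cross_validate(X, y, groups, GPConfig(k_folds=15, sigma_log=0.1))


def test_linear_baseline_is_exact_on_linear_data():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 4))
    y = X @ rng.normal(size=4)
    fits = fit_baselines(X, y, GPConfig(sigma_log=0.01, n_restarts=2), blocks=((0, 2), (2, 4)))
    pred = predict(fits["linear"], X)
    ss_res = ((pred.mean - y) ** 2).mean()
    assert 1.0 - ss_res / y.var() >= 0.99
    assert fits["additive"].config.kernel == "additive_matern"


def test_noise_sensitivity_table_shape():
    X, y = _toy(n=40)
    groups = [f"v{i}" for i in range(40)]
    out = noise_sensitivity_curve(X, y, groups, [0.1], GPConfig(sigma_log=0.1, k_folds=4, n_restarts=1))
    assert len(out) == 1
    out3 = noise_sensitivity_curve(
        X, y, groups, [0.01, 0.1, 1.0], GPConfig(sigma_log=0.1, k_folds=4, n_restarts=1)
    )
    assert len(out3) == 3
    assert list(out3["sigma_log"]) == [0.01, 0.1, 1.0]


def test_predict_rejects_feature_width_mismatch():
    X, y = _toy()
    fit = fit_gp(X, y, GPConfig(sigma_log=0.1, n_restarts=1))
    with pytest.raises(ValueError, match="width"):
        predict(fit, np.zeros((2, 5)))


def test_predict_is_batch_order_invariant():
    X, y = _toy(n=15)
    fit = fit_gp(X, y, GPConfig(sigma_log=0.1, n_restarts=1))
    Xs = np.random.default_rng(3).normal(size=(8, 3))
    perm = np.random.default_rng(4).permutation(8)
    p1 = predict(fit, Xs)
    p2 = predict(fit, Xs[perm])
    assert np.allclose(p1.mean[perm], p2.mean)
    assert np.allclose(p1.std[perm], p2.std)
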