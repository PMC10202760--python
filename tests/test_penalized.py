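import numpy as np
import pytest

from ssvslab.design import standardize
from ssvslab.penalized import (CvResult, adaptive_lasso, build_lasso_path,
                               cv_tune, elastic_net, entry_lambda_scores,
                               lasso_1se, lasso_bic, lasso_min, make_folds,
                               select_1se, select_min, _path_coefs)


def soft_threshold(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


# ---------------------------------------------------------------- paths


def test_path_endpoints(regression_design):
    path = build_lasso_path(regression_design)
    assert np.all(np.diff(path.lambdas) < 0)
    # at lambda_max every coefficient is zero (subgradient condition)
    assert np.all(path.coefficients[0] == 0.0)
    # unpenalized limit reproduces OLS on an n > p design
    ols, *_ = np.linalg.lstsq(regression_design.X, regression_design.y, rcond=None)
    tiny = _path_coefs(regression_design.X, regression_design.y, np.array([1e-10]))
    np.testing.assert_allclose(tiny[0], ols, atol=1e-6)


def test_univariate_path_is_soft_thresholding():
    rng = np.random.default_rng(5)
    n = 40
    x = rng.standard_normal(n)
    x = (x - x.mean())
    x *= np.sqrt(n / (x @ x))          # x'x = n exactly
    y = 0.9 * x + rng.standard_normal(n)
    y = y - y.mean()
    lambdas = np.geomspace(np.abs(x @ y) / n, 1e-3 * np.abs(x @ y) / n, 30)
    coefs = _path_coefs(x[:, None], y, lambdas)[:, 0]
    expected = soft_threshold(x @ y / n, lambdas)
    np.testing.assert_allclose(coefs, expected, atol=1e-8)


def test_orthonormal_design_closed_form():
    # columns with X'X = n I: every path point is coordinate-wise
    # soft-thresholding of the univariate projections
    rng = np.random.default_rng(8)
    n, p = 48, 4
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    X = Q * np.sqrt(n)
    y = X @ np.array([1.0, -0.5, 0.0, 0.2]) + rng.standard_normal(n)
    y -= y.mean()
    z = X.T @ y / n
    lambdas = np.geomspace(np.abs(z).max(), 1e-3 * np.abs(z).max(), 25)
    coefs = _path_coefs(X, y, lambdas)
    np.testing.assert_allclose(coefs, soft_threshold(z[None, :], lambdas[:, None]),
                               atol=1e-8)


def test_lasso_kkt_conditions(regression_design):
    # independent optimality check of the penalized objective: the
    # subgradient condition |x_j'r|/n <= lambda, with equality and sign
    # match on the active set
    path = build_lasso_path(regression_design)
    X, y, n = regression_design.X, regression_design.y, regression_design.n
    for g in (10, 50, 90):
        lam, beta = path.lambdas[g], path.coefficients[g]
        grad = X.T @ (y - X @ beta) / n
        active = beta != 0
        np.testing.assert_allclose(grad[active], lam * np.sign(beta[active]),
                                   atol=1e-6)
        assert np.all(np.abs(grad[~active]) <= lam + 1e-6)


def test_entry_lambda_scores(regression_design):
    path = build_lasso_path(regression_design)
    scores = entry_lambda_scores(path)
    assert scores.shape == (regression_design.p,)
    assert np.all((scores >= 0) & (scores <= 1))
    # strongest predictor enters first
    assert scores.argmax() == 0
    # thresholding the scores at each grid lambda reproduces a path support
    g = 40
    support_from_scores = scores >= path.lambdas[g] / path.lambdas[0]
    assert np.all(path.supports[g] <= support_from_scores)


# ------------------------------------------------------------------- CV


def test_fold_assignment_balance_and_determinism():
    folds = make_folds(25, 10, seed=3)
    sizes = np.bincount(folds)
    assert sizes.max() - sizes.min() <= 1
    assert np.array_equal(folds, make_folds(25, 10, seed=3))
    assert not np.array_equal(folds, make_folds(25, 10, seed=4))
    with pytest.raises(ValueError):
        make_folds(5, 1, seed=0)
    with pytest.raises(ValueError):
        make_folds(5, 6, seed=0)


def test_loo_when_k_equals_n(regression_design):
    sub = standardize(regression_design.X[:10], regression_design.y[:10])
    cv = cv_tune(sub, K=10, seed=0)
    assert np.bincount(cv.fold_assignment).tolist() == [1] * 10


def test_cv_deterministic(regression_design):
    a = cv_tune(regression_design, K=10, seed=1)
    b = cv_tune(regression_design, K=10, seed=1)
    np.testing.assert_array_equal(a.mean_cv_mse, b.mean_cv_mse)
    np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
    assert np.all(a.se_cv_mse >= 0)


def _cv(lambdas, mses, ses):
    return CvResult(lambdas=np.asarray(lambdas, float),
                    mean_cv_mse=np.asarray(mses, float),
                    se_cv_mse=np.asarray(ses, float),
                    fold_assignment=np.zeros(1, int))


def test_selection_rules_on_tiny_grids():
    # brute-force 3-point grid: min at .1; 1SE bound 4+1=5 admits .5
    cv = _cv([1.0, 0.5, 0.1], [10.0, 5.0, 4.0], [1.0, 1.0, 1.0])
    assert select_min(cv) == 0.1
    assert select_1se(cv) == 0.5
    # zero SEs collapse the 1SE rule onto the minimum
    cv = _cv([1.0, 0.5, 0.1], [9.0, 6.0, 3.0], [0.0, 0.0, 0.0])
    assert select_1se(cv) == select_min(cv) == 0.1
    # flat profile: the largest penalty wins both rules
    cv = _cv([1.0, 0.5, 0.1], [4.0, 4.0, 4.0], [1.0, 1.0, 1.0])
    assert select_min(cv) == 1.0
    assert select_1se(cv) == 1.0
    with pytest.raises(ValueError):
        select_min(_cv([], [], []))


def test_one_se_never_below_min(rng):
    for seed in range(5):
        g = np.random.default_rng(seed)
        X = g.standard_normal((40, 8))
        y = X[:, 0] + g.standard_normal(40)
        data = standardize(X, y)
        cv = cv_tune(data, K=5, seed=seed)
        assert select_1se(cv) >= select_min(cv)


# ------------------------------------------------------------ the five fits


def test_lasso_min_and_1se_fits(regression_design):
    fit_min = lasso_min(regression_design, seed=0)
    fit_1se = lasso_1se(regression_design, seed=0)
    assert fit_min.method == "lasso_min" and fit_1se.method == "lasso_1se"
    for fit in (fit_min, fit_1se):
        assert np.array_equal(fit.support, fit.coefficients != 0)
    assert fit_1se.lambda_ >= fit_min.lambda_
    # the informative predictors survive in the CV-min fit
    assert fit_min.support[0] and fit_min.support[2]


def test_lasso_bic_prefers_parsimony_by_formula(regression_design):
    # the BIC trade-off: n ln(RSS/n) + k ln(n); verified against direct
    # enumeration of candidate supports along the same path
    path = build_lasso_path(regression_design)
    cv = cv_tune(regression_design, seed=0, lambdas=path.lambdas)
    lam_min, lam_1se = select_min(cv), select_1se(cv)
    fit = lasso_bic(regression_design, path, lam_min, lam_1se)

    X, y, n = regression_design.X, regression_design.y, regression_design.n
    mask = (path.lambdas >= lam_min) & (path.lambdas <= lam_1se)
    best_bic, best_k = np.inf, None
    for support in {tuple(r) for r in (path.coefficients[mask] != 0)}:
        idx = np.flatnonzero(np.array(support))
        beta = np.zeros(X.shape[1])
        if idx.size:
            beta[idx], *_ = np.linalg.lstsq(X[:, idx], y, rcond=None)[:1]
        rss = float(((y - X @ beta) ** 2).sum())
        bic = n * np.log(rss / n) + (idx.size + 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, idx.size
    assert int(fit.support.sum()) == best_k
    # estimates are an unregularized refit: they satisfy the normal equations
    idx = np.flatnonzero(fit.support)
    resid = y - X @ fit.coefficients
    np.testing.assert_allclose(X[:, idx].T @ resid, 0.0, atol=1e-8)


def test_lasso_bic_degenerate_range(regression_design):
    path = build_lasso_path(regression_design)
    lam = path.lambdas[50]
    fit = lasso_bic(regression_design, path, lam, lam)
    support = path.coefficients[50] != 0
    assert np.array_equal(fit.support, support)
    with pytest.raises(ValueError):
        lasso_bic(regression_design, path, path.lambdas[10], path.lambdas[20])


def test_adaptive_weights_and_gamma_zero(regression_design):
    fit = adaptive_lasso(regression_design, gamma=1.0, seed=0)
    ols, *_ = np.linalg.lstsq(regression_design.X, regression_design.y, rcond=None)
    np.testing.assert_allclose(fit.weights, 1.0 / np.abs(ols), rtol=1e-10)
    # gamma = 0 gives unit weights: identical to ordinary lasso under the
    # same folds and tuning rule
    folds = make_folds(regression_design.n, 10, seed=2)
    plain = lasso_min(regression_design, fold_assignment=folds)
    unweighted = adaptive_lasso(regression_design, gamma=0.0,
                                fold_assignment=folds, rule="min")
    np.testing.assert_allclose(unweighted.coefficients, plain.coefficients,
                               atol=1e-10)


def test_adaptive_shrinks_large_effects_less_than_lasso():
    # a large effect is penalized less by the adaptive weights, so its
    # estimate sits closer to OLS than the plain lasso(min) estimate
    rng = np.random.default_rng(31)
    X = rng.standard_normal((200, 8))
    y = 1.5 * X[:, 0] + rng.standard_normal(200)
    data = standardize(X, y)
    folds = make_folds(200, 10, seed=1)
    plain = lasso_min(data, fold_assignment=folds)
    adaptive = adaptive_lasso(data, fold_assignment=folds, rule="min")
    ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    assert abs(adaptive.coefficients[0] - ols[0]) < abs(plain.coefficients[0] - ols[0])


def test_adaptive_requires_overdetermined_system():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((6, 8))
    y = rng.standard_normal(6)
    from ssvslab.design import StandardizedDesign
    data = StandardizedDesign(X=X, y=y - y.mean(), column_means=np.zeros(8),
                              column_sds=np.ones(8), y_mean=float(y.mean()))
    with pytest.raises(ValueError, match="ridge"):
        adaptive_lasso(data)


def test_elastic_net_alpha_one_is_lasso(regression_design):
    folds = make_folds(regression_design.n, 10, seed=5)
    enet = elastic_net(regression_design, alpha_grid=[1.0], fold_assignment=folds)
    plain = lasso_min(regression_design, fold_assignment=folds)
    assert enet.l1_ratio == 1.0
    np.testing.assert_allclose(enet.coefficients, plain.coefficients, atol=1e-8)
    with pytest.raises(ValueError):
        elastic_net(regression_design, alpha_grid=[0.0])


def test_elastic_net_grouping_of_duplicated_predictors():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(60)
    z = rng.standard_normal(60)
    X = np.column_stack([x, x, z])          # exact duplicate pair
    y = 2.0 * x + 0.5 * z + 0.3 * rng.standard_normal(60)
    data = standardize(X, y)
    fit = elastic_net(data, alpha_grid=[0.5], seed=3)
    assert fit.coefficients[0] != 0 and fit.coefficients[1] != 0
    # the ridge component splits the shared signal evenly
    assert fit.coefficients[0] == pytest.approx(fit.coefficients[1], rel=1e-3)
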