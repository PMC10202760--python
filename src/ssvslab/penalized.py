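"""Frequentist comparators: lasso(min), lasso(1SE), lasso(BIC), adaptive lasso, elastic net.

All five methods operate on a :class:`~ssvslab.design.StandardizedDesign` and
are tuned by 10-fold cross-validation on a shared, seeded fold assignment so
that differences between methods are not fold noise.

Penalty parameterization follows the coordinate-descent convention used by
glmnet and scikit-learn: the lasso objective is

    (1 / 2n) * ||y - X b||^2 + lambda * ||b||_1,

so the smallest penalty that zeroes every coefficient is
lambda_max = max_j |x_j' y| / n.  Paths are computed on a log-spaced grid of
100 values from lambda_max down to 1e-3 * lambda_max.  The elastic net mixes
an l1 fraction ``alpha`` with an l2 fraction ``1 - alpha``; ``alpha = 1``
is exactly the lasso.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.linear_model import enet_path, lasso_path

from .design import StandardizedDesign

__all__ = [
    "LambdaPath",
    "CvResult",
    "PenalizedFit",
    "build_lasso_path",
    "make_folds",
    "cv_tune",
    "select_min",
    "select_1se",
    "lasso_min",
    "lasso_1se",
    "lasso_bic",
    "adaptive_lasso",
    "elastic_net",
    "entry_lambda_scores",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass(frozen=True)
class LambdaPath:
    """Solution path over a decreasing penalty grid."""

    lambdas: np.ndarray        # strictly decreasing
    coefficients: np.ndarray   # (grid, p)
    intercepts: np.ndarray     # (grid,); zero for centered data

    @property
    def supports(self) -> np.ndarray:
        return self.coefficients != 0


@dataclass(frozen=True)
class CvResult:
    """Cross-validated held-out MSE along a penalty grid."""

    lambdas: np.ndarray
    mean_cv_mse: np.ndarray
    se_cv_mse: np.ndarray      # standard error across the K folds
    fold_assignment: np.ndarray
    seed: Optional[int] = None


@dataclass(frozen=True)
class PenalizedFit:
    """One fitted frequentist method."""

    method: str                # lasso_min | lasso_1se | lasso_bic | adaptive | elastic_net
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    l1_ratio: float = 1.0
    weights: Optional[np.ndarray] = None   # adaptive-lasso penalty weights
    names: list = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        return self.coefficients != 0


def _lambda_grid(X: np.ndarray, y: np.ndarray, grid_size: int, eps: float,
                 l1_ratio: float = 1.0) -> np.ndarray:
    lam_max = np.max(np.abs(X.T @ y)) / (X.shape[0] * l1_ratio)
    return np.geomspace(lam_max, eps * lam_max, grid_size)


def _path_coefs(X, y, lambdas, l1_ratio=1.0) -> np.ndarray:
    """Coordinate-descent path coefficients, shape (grid, p)."""
    if l1_ratio == 1.0:
        _, coefs, _ = lasso_path(X, y, alphas=lambdas, tol=1e-10, max_iter=100000)
    else:
        _, coefs, _ = enet_path(X, y, alphas=lambdas, l1_ratio=l1_ratio,
                                tol=1e-10, max_iter=100000)
    return coefs.T


def build_lasso_path(data: StandardizedDesign, grid_size: int = 100,
                     eps: float = 1e-3) -> LambdaPath:
    """Lasso solution path on the standardized data."""
    if data.p == 0:
        raise ValueError("no predictors")
    lambdas = _lambda_grid(data.X, data.y, grid_size, eps)
    coefs = _path_coefs(data.X, data.y, lambdas)
    return LambdaPath(lambdas=lambdas, coefficients=coefs,
                      intercepts=np.zeros(len(lambdas)))


def make_folds(n: int, K: int, seed: int) -> np.ndarray:
    """Seeded random partition into K folds whose sizes differ by at most 1."""
    if K < 2 or K > n:
        raise ValueError("need 2 <= K <= n")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    assignment[rng.permutation(n)] = np.arange(n) % K
    return assignment


def cv_tune(data: StandardizedDesign,
            path_builder: Optional[Callable] = None,
            K: int = 10, seed: int = 0,
            fold_assignment: Optional[np.ndarray] = None,
            lambdas: Optional[np.ndarray] = None) -> CvResult:
    """K-fold cross-validation of held-out MSE along a penalty grid.

    ``path_builder(X, y, lambdas) -> (grid, p) coefficients`` defaults to the
    lasso path.  Each training fold is re-centered so its intercept is
    honestly estimated; predictors keep the full-sample scaling.
    Deterministic given the seed (or an explicit fold assignment).
    """
    X, y, n = data.X, data.y, data.n
    if path_builder is None:
        path_builder = _path_coefs
    if fold_assignment is None:
        fold_assignment = make_folds(n, K, seed)
    else:
        K = int(fold_assignment.max()) + 1
    if lambdas is None:
        lambdas = _lambda_grid(X, y, 100, 1e-3)

    fold_mse = np.empty((K, len(lambdas)))
    for k in range(K):
        test = fold_assignment == k
        Xtr, ytr = X[~test], y[~test]
        mx, my = Xtr.mean(axis=0), ytr.mean()
        coefs = path_builder(Xtr - mx, ytr - my, lambdas)
        pred = (X[test] - mx) @ coefs.T + my
        fold_mse[k] = np.mean((y[test, None] - pred) ** 2, axis=0)

    return CvResult(
        lambdas=np.asarray(lambdas),
        mean_cv_mse=fold_mse.mean(axis=0),
        se_cv_mse=fold_mse.std(axis=0, ddof=1) / np.sqrt(K),
        fold_assignment=fold_assignment,
        seed=seed,
    )


def select_min(cv: CvResult) -> float:
    """Penalty minimizing mean CV error; the largest such penalty on ties."""
    if len(cv.lambdas) == 0:
        raise ValueError("empty penalty grid")
    best = cv.mean_cv_mse.min()
    return float(cv.lambdas[cv.mean_cv_mse == best].max())


def select_1se(cv: CvResult) -> float:
    """Largest penalty whose mean CV error is within one SE of the minimum."""
    if len(cv.lambdas) == 0:
        raise ValueError("empty penalty grid")
    lam_min = select_min(cv)
    at_min = np.flatnonzero(cv.lambdas == lam_min)[0]
    bound = cv.mean_cv_mse[at_min] + cv.se_cv_mse[at_min]
    return float(cv.lambdas[cv.mean_cv_mse <= bound].max())


def _coefs_at(path: LambdaPath, lam: float) -> np.ndarray:
    idx = int(np.argmin(np.abs(path.lambdas - lam)))
    return path.coefficients[idx].copy()


def lasso_min(data: StandardizedDesign, K: int = 10, seed: int = 0,
              fold_assignment=None, path: Optional[LambdaPath] = None,
              cv: Optional[CvResult] = None) -> PenalizedFit:
    """Lasso tuned by the CV-minimum rule."""
    if path is None:
        path = build_lasso_path(data)
    if cv is None:
        cv = cv_tune(data, K=K, seed=seed, fold_assignment=fold_assignment,
                     lambdas=path.lambdas)
    lam = select_min(cv)
    return PenalizedFit("lasso_min", _coefs_at(path, lam), 0.0, lam,
                        names=list(data.names))


def lasso_1se(data: StandardizedDesign, K: int = 10, seed: int = 0,
              fold_assignment=None, path: Optional[LambdaPath] = None,
              cv: Optional[CvResult] = None) -> PenalizedFit:
    """Lasso tuned by the one-standard-error rule (more shrinkage)."""
    if path is None:
        path = build_lasso_path(data)
    if cv is None:
        cv = cv_tune(data, K=K, seed=seed, fold_assignment=fold_assignment,
                     lambdas=path.lambdas)
    lam = select_1se(cv)
    return PenalizedFit("lasso_1se", _coefs_at(path, lam), 0.0, lam,
                        names=list(data.names))


def _ols(X: np.ndarray, y: np.ndarray, support: np.ndarray):
    """Least-squares refit on the selected columns; returns (coefs, rss)."""
    p = X.shape[1]
    beta = np.zeros(p)
    idx = np.flatnonzero(support)
    if idx.size:
        sol, _, _, _ = np.linalg.lstsq(X[:, idx], y, rcond=None)
        beta[idx] = sol
    resid = y - X @ beta
    return beta, float(resid @ resid)


def lasso_bic(data: StandardizedDesign, path: LambdaPath,
              lambda_min: float, lambda_1se: float) -> PenalizedFit:
    """Unpenalized refit of candidate lasso supports, chosen by BIC.

    Candidates are the distinct nonzero patterns along the path between the
    CV-min and 1SE penalties (inclusive).  Each is refit by OLS and scored
    with BIC = n ln(RSS/n) + k ln(n), k counting the coefficients plus the
    intercept.  Ties favor the smaller support.
    """
    if lambda_1se < lambda_min:
        raise ValueError("lambda_1se must be >= lambda_min")
    n = data.n
    mask = (path.lambdas >= lambda_min) & (path.lambdas <= lambda_1se)
    supports = {tuple(row) for row in path.supports[mask]}
    best = None
    for support in sorted(supports, key=sum):
        support = np.array(support, dtype=bool)
        k = int(support.sum()) + 1
        if k - 1 >= n:
            warnings.warn(f"candidate support of size {k - 1} >= n skipped")
            continue
        beta, rss = _ols(data.X, data.y, support)
        bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, beta)
    if best is None:
        raise ValueError("no admissible candidate support")
    beta = best[1]
    return PenalizedFit("lasso_bic", beta, 0.0, float(lambda_min),
                        names=list(data.names))


def adaptive_lasso(data: StandardizedDesign, gamma: float = 1.0, K: int = 10,
                   seed: int = 0, fold_assignment=None,
                   rule: str = "1se") -> PenalizedFit:
    """Adaptive lasso: weighted l1 penalty with OLS-based weights.

    Weights are w_j = 1 / |b_j^OLS|^gamma; the weighted problem is solved by
    rescaling column j by |b_j^OLS|^gamma, running an ordinary lasso, and
    scaling the solution back.  The penalty is chosen by 10-fold CV with the
    one-standard-error rule by default (the default solution extracted by
    the usual CV lasso tooling); pass ``rule="min"`` for the CV-minimum
    choice, under which gamma = 0 reduces exactly to lasso(min).
    """
    X, y = data.X, data.y
    n, p = X.shape
    if n <= p:
        raise ValueError("adaptive lasso needs n > p for the OLS initial "
                         "estimator; consider a ridge initialization")
    beta_ols, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("singular X'X; consider a ridge initialization")
    scale = np.abs(beta_ols) ** gamma        # = 1 / w_j
    Xw = X * scale
    lambdas = _lambda_grid(Xw, y, 100, 1e-3)
    scaled = StandardizedDesign(X=Xw, y=y, column_means=data.column_means,
                                column_sds=data.column_sds, y_mean=data.y_mean,
                                names=data.names)
    cv = cv_tune(scaled, K=K, seed=seed, fold_assignment=fold_assignment,
                 lambdas=lambdas)
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    lam = select_min(cv) if rule == "min" else select_1se(cv)
    coefs_w = _path_coefs(Xw, y, lambdas)[int(np.argmin(np.abs(lambdas - lam)))]
    beta = coefs_w * scale
    with np.errstate(divide="ignore"):
        weights = np.where(scale > 0, 1.0 / np.where(scale > 0, scale, 1), np.inf)
    return PenalizedFit("adaptive", beta, 0.0, lam, weights=weights,
                        names=list(data.names))


def elastic_net(data: StandardizedDesign,
                alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                K: int = 10, seed: int = 0,
                fold_assignment=None) -> PenalizedFit:
    """Elastic net with the (alpha, lambda) pair chosen by joint CV-min.

    ``alpha`` is the l1 fraction of the penalty; each alpha gets its own
    log-spaced lambda grid and the same folds, and the global minimizer of
    mean CV MSE wins.
    """
    alpha_grid = [a for a in alpha_grid if a > 0]
    if not alpha_grid:
        raise ValueError("alpha_grid must contain a positive l1 fraction "
                         "(pure ridge never selects)")
    if fold_assignment is None:
        fold_assignment = make_folds(data.n, K, seed)
    best = None
    for alpha in alpha_grid:
        lambdas = _lambda_grid(data.X, data.y, 100, 1e-3, l1_ratio=alpha)
        builder = lambda X, y, lams, a=alpha: _path_coefs(X, y, lams, l1_ratio=a)
        cv = cv_tune(data, path_builder=builder, fold_assignment=fold_assignment,
                     lambdas=lambdas)
        i = int(np.argmin(cv.mean_cv_mse))
        if best is None or cv.mean_cv_mse[i] < best[0]:
            best = (cv.mean_cv_mse[i], alpha, float(cv.lambdas[i]))
    _, alpha, lam = best
    coefs = _path_coefs(data.X, data.y, np.array([lam]), l1_ratio=alpha)[0]
    return PenalizedFit("elastic_net", coefs, 0.0, lam, l1_ratio=alpha,
                        names=list(data.names))


def entry_lambda_scores(path: LambdaPath) -> np.ndarray:
    """Per-predictor selection score: the largest penalty at which it enters.

    Normalized by lambda_max to lie in [0, 1]; predictors never entering the
    path score 0.  Sweeping a threshold over these scores reproduces the
    family of lasso supports along the path, which is the natural ROC
    threshold family for the lasso.
    """
    lam_max = path.lambdas[0]
    scores = np.zeros(path.coefficients.shape[1])
    for g in range(len(path.lambdas)):
        newly = (path.coefficients[g] != 0) & (scores == 0)
        scores[newly] = path.lambdas[g] / lam_max
    return scores
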