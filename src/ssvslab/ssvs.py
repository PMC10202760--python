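"""Stochastic search variable selection (SSVS) for linear regression.

The model is the usual Gaussian linear regression augmented with one binary
inclusion indicator per predictor:

    y_i = beta0 + sum_j delta_j * x_ij * beta_j + eps_i,   eps_i ~ N(0, sigma^2)

with a point-mass spike-and-slab prior on the coefficients,

    beta_j | delta_j = 1  ~  N(0, tau^2)        (the "slab", default tau^2 = 10)
    beta_j | delta_j = 0  =  0                  (the point-mass "spike")
    delta_j               ~  Bernoulli(pi_j)    (default pi_j = 0.5)

and noninformative nuisance priors: a flat prior on the intercept and
1/sigma^2 ~ Gamma(shape a, rate b) with a = b = 0.01.  The slab variance is
an unconditional N(0, tau^2) — it is deliberately *not* scaled by sigma^2.

Posterior exploration is a systematic-scan Gibbs sampler.  For each
predictor in turn the pair (delta_j, beta_j) is updated jointly from its
conditional given the partial residual r = y - beta0 - X_{-j} beta_{-j}:
with v_j = 1 / (x_j'x_j / sigma^2 + 1 / tau^2) and m_j = v_j x_j'r / sigma^2,
the inclusion odds are pi R_j / (1 - pi) with

    R_j = sqrt(v_j / tau^2) * exp(m_j^2 / (2 v_j)),

then beta_j ~ N(m_j, v_j) if included, else exactly 0.  The key posterior
summary is the marginal inclusion probability (MIP): the proportion of
retained draws with delta_j = 1.  The "median model" keeps predictors with
MIP above 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .design import StandardizedDesign

__all__ = [
    "SsvsPrior",
    "SsvsConfig",
    "SsvsDraws",
    "SsvsSummary",
    "inclusion_probability",
    "run_ssvs",
    "summarize",
]


@dataclass(frozen=True)
class SsvsPrior:
    """Spike-and-slab prior hyperparameters.

    slab_variance : variance tau^2 of the normal slab (default 10).
    inclusion_prob : prior inclusion probability pi, scalar or per-predictor
        vector, strictly inside (0, 1) (default 0.5).
    gamma_shape, gamma_rate : shape a and rate b of the gamma prior on the
        residual precision 1/sigma^2 (default 0.01 each).
    """

    slab_variance: float = 10.0
    inclusion_prob: object = 0.5
    gamma_shape: float = 0.01
    gamma_rate: float = 0.01

    def __post_init__(self):
        if self.slab_variance <= 0:
            raise ValueError("slab_variance must be positive")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        pi = np.atleast_1d(np.asarray(self.inclusion_prob, dtype=float))
        if np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("inclusion_prob must lie strictly in (0, 1)")

    def pi_vector(self, p: int) -> np.ndarray:
        pi = np.atleast_1d(np.asarray(self.inclusion_prob, dtype=float))
        if pi.size == 1:
            return np.full(p, pi[0])
        if pi.size != p:
            raise ValueError(f"inclusion_prob has length {pi.size}, expected {p}")
        return pi.copy()


@dataclass(frozen=True)
class SsvsConfig:
    """Chain length and reproducibility settings.

    total_draws / burn_in default to 20,000 / 5,000; the first ``burn_in``
    states are discarded as warm-up.  ``random_scan`` permutes the predictor
    update order each iteration (off by default, for reproducibility of the
    systematic scan).  ``fix_sigma2`` holds the residual variance at a known
    value instead of sampling it — useful for exact-posterior cross-checks.
    """

    total_draws: int = 20000
    burn_in: int = 5000
    seed: int = 0
    random_scan: bool = False
    fix_sigma2: Optional[float] = None

    def __post_init__(self):
        if self.total_draws <= 0:
            raise ValueError("total_draws must be positive")
        if not 0 <= self.burn_in < self.total_draws:
            raise ValueError("burn_in must satisfy 0 <= burn_in < total_draws")
        if self.fix_sigma2 is not None and self.fix_sigma2 <= 0:
            raise ValueError("fix_sigma2 must be positive when given")


@dataclass(frozen=True)
class SsvsDraws:
    """Retained MCMC draws, stored as parallel arrays of length R = total - burn_in."""

    beta0: np.ndarray       # (R,)
    beta: np.ndarray        # (R, p); exact zeros where delta == 0
    delta: np.ndarray       # (R, p) uint8
    sigma2: np.ndarray      # (R,)
    prior: SsvsPrior
    config: SsvsConfig
    names: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[1]


@dataclass(frozen=True)
class SsvsSummary:
    """Posterior summaries: MIPs, model-averaged coefficients, median model."""

    mips: np.ndarray
    avg_b: np.ndarray           # averaged over all draws, zeros included
    avg_b_nonzero: np.ndarray   # averaged over draws with delta_j = 1; NaN if MIP = 0
    median_model: np.ndarray    # indices with MIP strictly above the threshold
    mip_threshold: float
    names: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.names or [f"x{j + 1}" for j in range(len(self.mips))]
        in_model = np.zeros(len(self.mips), dtype=bool)
        in_model[self.median_model] = True
        return pd.DataFrame(
            {
                "predictor": names,
                "mip": self.mips,
                "avg_b": self.avg_b,
                "avg_b_nonzero": self.avg_b_nonzero,
                "in_median_model": in_model,
            }
        )


def inclusion_probability(xtx_j: float, xtr_j: float, sigma2: float,
                          prior: SsvsPrior, j: int = 0) -> float:
    """Conditional probability that predictor j is included, given the partial residual.

    Implements the spike-vs-slab Bernoulli update: with posterior slab
    variance ``v = 1/(xtx_j/sigma2 + 1/tau2)`` and mean ``m = v*xtr_j/sigma2``,
    the likelihood ratio is ``R = sqrt(v/tau2) * exp(m^2/(2v))`` and

        P(delta_j = 1 | .) = pi * R / (pi * R + 1 - pi).

    Computed on the log-odds scale for numerical stability.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if xtx_j <= 0:
        raise ValueError("xtx_j must be positive")
    tau2 = prior.slab_variance
    pi_arr = np.atleast_1d(np.asarray(prior.inclusion_prob, dtype=float))
    pi = float(pi_arr[0] if pi_arr.size == 1 else pi_arr[j])
    v = 1.0 / (xtx_j / sigma2 + 1.0 / tau2)
    m = v * xtr_j / sigma2
    log_odds = math.log(pi / (1.0 - pi)) + 0.5 * math.log(v / tau2) + 0.5 * m * m / v
    return 1.0 / (1.0 + math.exp(-log_odds))


@njit(cache=True)
def _gibbs_kernel(XtX, Xty, yty, n, tau2, logit_pi, prior_b, total, burn,
                  U, Z, Z0, G, fix_s2, s2_init, beta_init, perms, use_perms):
    """Sufficient-statistic Gibbs sweep.

    All random variates are pre-drawn (U: uniforms, Z/Z0: standard normals,
    G: Gamma(a + n/2, 1) variates), so the kernel is pure deterministic
    arithmetic.  Columns of X are centered, hence the intercept drops out of
    every coefficient update and has conditional N(0, sigma^2/n).
    Returns an error flag: 0 ok, 1 divergent sigma^2.
    """
    p = XtX.shape[0]
    R = total - burn
    beta = beta_init.copy()
    delta = np.ones(p, dtype=np.uint8)
    c = XtX @ beta                      # running XtX @ beta
    s2 = s2_init
    beta0 = 0.0

    out_beta = np.zeros((R, p))
    out_delta = np.zeros((R, p), dtype=np.uint8)
    out_beta0 = np.zeros(R)
    out_s2 = np.zeros(R)

    for t in range(total):
        for jj in range(p):
            j = perms[t % perms.shape[0], jj] if use_perms else jj
            xtx = XtX[j, j]
            xtr = Xty[j] - (c[j] - xtx * beta[j])
            v = 1.0 / (xtx / s2 + 1.0 / tau2)
            m = v * xtr / s2
            log_odds = logit_pi[j] + 0.5 * math.log(v / tau2) + 0.5 * m * m / v
            p1 = 1.0 / (1.0 + math.exp(-log_odds))
            if U[t, j] < p1:
                new_b = m + math.sqrt(v) * Z[t, j]
                delta[j] = 1
            else:
                new_b = 0.0
                delta[j] = 0
            d = new_b - beta[j]
            if d != 0.0:
                beta[j] = new_b
                for k in range(p):
                    c[k] += XtX[k, j] * d
        # periodic refresh of the running product to cap drift
        if t % 1000 == 999:
            c = XtX @ beta

        beta0 = math.sqrt(s2 / n) * Z0[t]

        rss = yty - 2.0 * np.dot(beta, Xty) + np.dot(beta, c) + n * beta0 * beta0
        if rss < 0.0:
            rss = 0.0
        if fix_s2 > 0.0:
            s2 = fix_s2
        else:
            s2 = (prior_b + 0.5 * rss) / G[t]
        if not np.isfinite(s2) or s2 <= 0.0:
            return out_beta0, out_beta, out_delta, out_s2, 1

        if t >= burn:
            r = t - burn
            out_beta0[r] = beta0
            for k in range(p):
                out_beta[r, k] = beta[k]
                out_delta[r, k] = delta[k]
            out_s2[r] = s2

    return out_beta0, out_beta, out_delta, out_s2, 0


def run_ssvs(data: StandardizedDesign, prior: SsvsPrior = SsvsPrior(),
             config: SsvsConfig = SsvsConfig()) -> SsvsDraws:
    """Run the spike-and-slab Gibbs sampler and return retained draws.

    Initialization: all indicators on, coefficients at the near-unpenalized
    ridge solution (penalty 1e-6), sigma^2 at that fit's residual variance —
    a high-likelihood starting point that shortens warm-up.  Two runs with
    the same data, prior, and config produce bit-identical draws.
    """
    X, y = data.X, data.y
    n, p = X.shape
    if p == 0:
        raise ValueError("no predictors")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    pi = prior.pi_vector(p)
    logit_pi = np.log(pi / (1.0 - pi))

    beta_init = np.linalg.solve(XtX + 1e-6 * np.eye(p), Xty)
    resid = y - X @ beta_init
    s2_init = float(resid @ resid / n)
    if s2_init <= 0:
        s2_init = 1e-8
    if config.fix_sigma2 is not None:
        s2_init = config.fix_sigma2

    rng = np.random.default_rng(config.seed)
    total = config.total_draws
    U = rng.random((total, p))
    Z = rng.standard_normal((total, p))
    Z0 = rng.standard_normal(total)
    G = rng.gamma(prior.gamma_shape + n / 2.0, 1.0, total)
    if config.random_scan:
        perms = np.argsort(rng.random((total, p)), axis=1).astype(np.int64)
        use_perms = True
    else:
        perms = np.zeros((1, p), dtype=np.int64)
        use_perms = False

    fix_s2 = config.fix_sigma2 if config.fix_sigma2 is not None else -1.0
    beta0_d, beta_d, delta_d, s2_d, err = _gibbs_kernel(
        XtX, Xty, yty, float(n), prior.slab_variance, logit_pi,
        prior.gamma_rate, total, config.burn_in,
        U, Z, Z0, G, float(fix_s2), s2_init, beta_init, perms, use_perms,
    )
    if err:
        raise FloatingPointError(
            "sigma^2 diverged during sampling; check the data scale or fix "
            "sigma2 via SsvsConfig(fix_sigma2=...)"
        )
    return SsvsDraws(beta0=beta0_d, beta=beta_d, delta=delta_d, sigma2=s2_d,
                     prior=prior, config=config, names=list(data.names))


def summarize(draws: SsvsDraws, mip_threshold: float = 0.5) -> SsvsSummary:
    """MIPs, model-averaged coefficients, and the median model.

    ``avg_b`` averages delta_j * beta_j over all retained draws (zeros
    included); ``avg_b_nonzero`` conditions on inclusion and is NaN for a
    predictor never included.  The identity avg_b = MIP * avg_b_nonzero holds
    exactly over the draws.  The median model uses a strict inequality: an
    exact tie at the threshold excludes the predictor.
    """
    if not 0 <= mip_threshold <= 1:
        raise ValueError("mip_threshold must lie in [0, 1]")
    if draws.n_retained == 0:
        raise ValueError("no retained draws")
    R = draws.n_retained
    counts = draws.delta.sum(axis=0).astype(float)
    mips = counts / R
    sums = draws.beta.sum(axis=0)      # beta is exactly 0 where delta == 0
    avg_b = sums / R
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_b_nonzero = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    median_model = np.flatnonzero(mips > mip_threshold)
    return SsvsSummary(mips=mips, avg_b=avg_b, avg_b_nonzero=avg_b_nonzero,
                       median_model=median_model, mip_threshold=mip_threshold,
                       names=list(draws.names))
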