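"""Synthetic benchmark data: correlated Gaussian predictors, sparse linear signal.

The study conditions cross sample size (n = 100 or 400) with the correlation
structure of p = 50 predictors arranged in blocks of 5.  Within a block the
correlation is exchangeable at rho (0, .4, or .8); between blocks it is zero.
Ten predictors carry true effects — two large (1.5), four medium (.9), four
small (.3) on the raw coefficient scale — placed in one of three patterns:

* ``independent`` : rho = 0, effects occupy positions 1-10;
* ``mixed``       : effects spread one per block (positions 1, 6, 11, ..., 46),
                    so every true effect sits among null neighbors;
* ``clustered``   : effects fill the first two blocks (positions 1-10), so
                    true effects are correlated with each other.

The outcome is y = X beta + eps with eps ~ N(0, sigma^2 I), sigma^2 = 1.
With independent predictors Var(Y) = beta'beta + 1 = 9.1, so the raw
coefficients (1.5, .9, .3) correspond to standardized effects of about
(.5, .3, .1); under clustering beta' Sigma beta grows and the standardized
effects shrink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scenario",
    "GeneratedDataset",
    "EFFECT_VALUES",
    "block_covariance",
    "true_beta",
    "generate",
    "standardized_effect",
    "effect_classes",
    "default_grid",
]

#: Raw generating coefficients for the ten true effects, in placement order.
EFFECT_VALUES = (1.5, 0.9, 0.9, 0.3, 0.3, 1.5, 0.9, 0.9, 0.3, 0.3)

_PATTERNS = ("independent", "mixed", "clustered")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition."""

    n: int
    rho: float = 0.0
    pattern: str = "independent"
    p: int = 50
    block_size: int = 5
    sigma2: float = 1.0
    effect_values: tuple = EFFECT_VALUES

    def __post_init__(self):
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}")
        if self.p % self.block_size != 0:
            raise ValueError("p must be divisible by block_size")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.pattern == "independent" and self.rho != 0:
            raise ValueError("independent pattern requires rho = 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def name(self) -> str:
        return f"{self.pattern}_rho{self.rho:g}_n{self.n}"


@dataclass(frozen=True)
class GeneratedDataset:
    X: np.ndarray
    y: np.ndarray
    true_beta: np.ndarray
    effect_class: list = field(default_factory=list)  # per predictor
    seed: int = 0
    scenario: Scenario = None


def block_covariance(p: int, block_size: int, rho: float) -> np.ndarray:
    """Block-diagonal covariance: unit diagonal, exchangeable rho within blocks.

    Positive definite for -1/(block_size-1) < rho < 1; the admissible range is
    enforced.  Eigenvalues per block are 1 + (block_size-1)rho (once) and
    1 - rho (block_size - 1 times).
    """
    if p % block_size != 0:
        raise ValueError("p must be divisible by block_size")
    if rho >= 1 or (block_size > 1 and rho <= -1.0 / (block_size - 1)):
        raise ValueError("rho outside the positive-definite range for this block size")
    block = np.full((block_size, block_size), rho)
    np.fill_diagonal(block, 1.0)
    out = np.zeros((p, p))
    for s in range(0, p, block_size):
        out[s:s + block_size, s:s + block_size] = block
    return out


def true_beta(scenario: Scenario) -> np.ndarray:
    """Raw generating coefficient vector for the scenario's effect pattern."""
    beta = np.zeros(scenario.p)
    vals = scenario.effect_values
    if scenario.pattern == "mixed":
        # one true effect per block: positions 0, block_size, 2*block_size, ...
        idx = np.arange(len(vals)) * scenario.block_size
    else:
        # independent and clustered: effects fill the leading positions
        idx = np.arange(len(vals))
    beta[idx] = vals
    return beta


def effect_classes(beta: np.ndarray) -> list:
    """Label each predictor null/small/medium/large by its raw |coefficient|."""
    labels = {0.0: "null", 0.3: "small", 0.9: "medium", 1.5: "large"}
    out = []
    for b in np.abs(beta):
        key = min(labels, key=lambda v: abs(v - b))
        out.append(labels[key])
    return out


def generate(scenario: Scenario, seed: int) -> GeneratedDataset:
    """Draw X ~ N(0, Sigma) and y = X beta + eps, eps ~ N(0, sigma^2 I)."""
    rng = np.random.default_rng(seed)
    sigma = block_covariance(scenario.p, scenario.block_size, scenario.rho)
    L = np.linalg.cholesky(sigma)
    X = rng.standard_normal((scenario.n, scenario.p)) @ L.T
    beta = true_beta(scenario)
    eps = rng.standard_normal(scenario.n) * np.sqrt(scenario.sigma2)
    y = X @ beta + eps
    return GeneratedDataset(X=X, y=y, true_beta=beta,
                            effect_class=effect_classes(beta),
                            seed=seed, scenario=scenario)


def standardized_effect(scenario: Scenario, j: int) -> float:
    """Standardized coefficient beta_j / sd(Y) for predictor j (0-based).

    sd(Y) = sqrt(beta' Sigma beta + sigma^2); with independent predictors
    this is sqrt(9.1) and the effects are about .497, .298, .099.
    """
    if not 0 <= j < scenario.p:
        raise ValueError("predictor index out of range")
    beta = true_beta(scenario)
    sigma = block_covariance(scenario.p, scenario.block_size, scenario.rho)
    var_y = float(beta @ sigma @ beta) + scenario.sigma2
    return float(beta[j] / np.sqrt(var_y))


def default_grid() -> list:
    """The full 10-condition grid: {independent, mixed x rho, clustered x rho} x n."""
    grid = []
    for n in (100, 400):
        grid.append(Scenario(n=n, rho=0.0, pattern="independent"))
        for pattern in ("mixed", "clustered"):
            for rho in (0.4, 0.8):
                grid.append(Scenario(n=n, rho=rho, pattern=pattern))
    return grid
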