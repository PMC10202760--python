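"""Standardized regression design.

Every selection method in this package operates on the same input: a
predictor matrix whose columns have been centered and scaled to unit
sample variance, and a centered outcome.  Standardizing first is what
makes a single penalty (or a single slab variance) apply evenly to
predictors measured on different scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StandardizedDesign:
    """Centered/scaled predictors plus centered outcome.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Predictors; each column has mean 0 and sample standard deviation 1
        (``ddof=1`` denominator).
    y : ndarray of shape (n,)
        Outcome, centered to mean 0 but not rescaled, so coefficients stay
        on the outcome's original units per standard deviation of X.
    column_means, column_sds : ndarray of shape (p,)
        Standardization metadata for mapping coefficients back to the raw
        predictor scale.
    y_mean : float
        Mean removed from the outcome.
    names : list of str
        Predictor names (generated ``x1..xp`` if the caller gave none).
    """

    X: np.ndarray
    y: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    y_mean: float
    names: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(raw_X, raw_y, names=None) -> StandardizedDesign:
    """Center and scale predictors to unit sample variance; center the outcome.

    Parameters
    ----------
    raw_X : array-like of shape (n, p)
    raw_y : array-like of shape (n,)
    names : sequence of str, optional
        Predictor names carried through to outputs.

    Raises
    ------
    ValueError
        On missing values, fewer than 3 observations, or a constant column
        (named in the message).
    """
    X = np.ascontiguousarray(raw_X, dtype=np.float64)
    y = np.ascontiguousarray(raw_y, dtype=np.float64).ravel()
    if X.ndim != 2:
        raise ValueError("raw_X must be a 2-D array")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"raw_y has length {y.shape[0]}, expected {n}")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError(
            "missing or non-finite values present; handle them before "
            "standardizing (e.g. listwise deletion)"
        )
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length does not match number of columns")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        bad = ", ".join(names[j] for j in constant)
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    Xs = (X - means) / sds
    y_mean = float(y.mean())
    return StandardizedDesign(
        X=Xs,
        y=y - y_mean,
        column_means=means,
        column_sds=sds,
        y_mean=y_mean,
        names=names,
    )
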