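"""Replication runner and selection-accuracy metrics.

For each simulated replication every requested method is fit on the same
standardized data, and three things are recorded per method: the selected
support (nonzero coefficients; for SSVS, MIP > .5), the coefficient
estimates (for SSVS the model-averaged estimates inclusive of zeros), and —
where the method has a natural threshold family — a per-predictor selection
score for ROC analysis (MIP for SSVS, entry penalty along the path for the
lasso).  Aggregation over replications yields inclusion rates by effect
class, coefficient bias and spread, mean AUC, and mean model size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import StandardizedDesign, standardize
from .penalized import (adaptive_lasso, build_lasso_path, cv_tune, elastic_net,
                        entry_lambda_scores, lasso_1se, lasso_bic, lasso_min,
                        make_folds, select_1se, select_min)
from .simulate import Scenario, generate
from .ssvs import SsvsConfig, SsvsPrior, run_ssvs, summarize

log = logging.getLogger(__name__)

ALL_METHODS = ("lasso_min", "lasso_1se", "lasso_bic", "adaptive",
               "elastic_net", "ssvs")
EFFECT_CLASS_ORDER = ("null", "small", "medium", "large")
#: Raw generating coefficient for each effect class (bias benchmark).
CLASS_TRUE_VALUE = {"null": 0.0, "small": 0.3, "medium": 0.9, "large": 1.5}


@dataclass(frozen=True)
class MethodResult:
    support: np.ndarray                 # bool (p,)
    estimates: np.ndarray               # float (p,)
    scores: Optional[np.ndarray] = None  # selection scores in [0,1], or None


@dataclass(frozen=True)
class ReplicationResult:
    scenario_name: str
    seed: int
    methods: dict                       # name -> MethodResult


@dataclass(frozen=True)
class ConditionSummary:
    scenario: Scenario
    reps: int
    n_failures: int
    inclusion: pd.DataFrame             # rows method, cols effect class, in %
    coefficients: pd.DataFrame          # (method, class) -> mean/bias/interval
    auc: dict                           # method -> mean AUC (scored methods)
    model_size: dict                    # method -> mean count selected

    def long_frame(self) -> pd.DataFrame:
        """Tidy long format: (condition, method, effect_class, metric, value)."""
        rows = []
        cond = self.scenario.name
        for method in self.inclusion.index:
            for cls in self.inclusion.columns:
                rows.append((cond, method, cls, "inclusion_rate",
                             self.inclusion.loc[method, cls]))
        for (method, cls), r in self.coefficients.iterrows():
            for metric in r.index:
                rows.append((cond, method, cls, metric, r[metric]))
        for method, v in self.auc.items():
            rows.append((cond, method, "all", "mean_auc", v))
        for method, v in self.model_size.items():
            rows.append((cond, method, "all", "mean_model_size", v))
        return pd.DataFrame(rows, columns=["condition", "method",
                                           "effect_class", "metric", "value"])


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve from a threshold sweep over the scores.

    At each distinct score t, sensitivity is the fraction of true effects
    with score >= t and specificity the fraction of nulls with score < t;
    tied scores share one ROC point, the (0,0) and (1,1) endpoints are
    appended, and the area is trapezoidal.  Equals the Mann-Whitney
    concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = truth.sum(), (~truth).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one positive and one negative")
    thresholds = np.unique(scores)[::-1]
    tpr = [(scores[truth] >= t).mean() for t in thresholds]
    fpr = [(scores[~truth] >= t).mean() for t in thresholds]
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    return float(np.trapezoid(tpr, fpr))


def fit_methods(data, methods: Sequence[str] = ALL_METHODS, seed: int = 0,
                ssvs_prior: Optional[SsvsPrior] = None,
                ssvs_config: Optional[SsvsConfig] = None,
                cv_folds: int = 10) -> dict:
    """Fit the requested methods on one dataset with one shared CV fold assignment."""
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; valid: {ALL_METHODS}")
    out = {}
    lasso_family = {"lasso_min", "lasso_1se", "lasso_bic"}
    folds = (make_folds(data.n, cv_folds, seed)
             if set(methods) - {"ssvs"} else None)

    if lasso_family & set(methods):
        path = build_lasso_path(data)
        cv = cv_tune(data, fold_assignment=folds, lambdas=path.lambdas)
        path_scores = entry_lambda_scores(path)
        if "lasso_min" in methods:
            fit = lasso_min(data, path=path, cv=cv)
            out["lasso_min"] = MethodResult(fit.support, fit.coefficients,
                                            path_scores)
        if "lasso_1se" in methods:
            fit = lasso_1se(data, path=path, cv=cv)
            out["lasso_1se"] = MethodResult(fit.support, fit.coefficients,
                                            path_scores)
        if "lasso_bic" in methods:
            fit = lasso_bic(data, path, select_min(cv), select_1se(cv))
            out["lasso_bic"] = MethodResult(fit.support, fit.coefficients)
    if "adaptive" in methods:
        fit = adaptive_lasso(data, fold_assignment=folds)
        out["adaptive"] = MethodResult(fit.support, fit.coefficients)
    if "elastic_net" in methods:
        fit = elastic_net(data, fold_assignment=folds)
        out["elastic_net"] = MethodResult(fit.support, fit.coefficients)
    if "ssvs" in methods:
        prior = ssvs_prior or SsvsPrior()
        config = ssvs_config or SsvsConfig()
        # The SSVS step scales the response to unit variance before sampling
        # (so the fixed slab applies on a scale-free metric, as the reference
        # software does for continuous outcomes) and back-transforms the
        # model-averaged estimates to the outcome's original units.
        sd_y = float(np.std(data.y, ddof=1))
        scaled = StandardizedDesign(
            X=data.X, y=data.y / sd_y, column_means=data.column_means,
            column_sds=data.column_sds, y_mean=data.y_mean, names=data.names)
        draws = run_ssvs(scaled, prior, SsvsConfig(
            total_draws=config.total_draws, burn_in=config.burn_in,
            seed=seed, random_scan=config.random_scan,
            fix_sigma2=config.fix_sigma2))
        summ = summarize(draws)
        out["ssvs"] = MethodResult(summ.mips > 0.5, summ.avg_b * sd_y, summ.mips)
    return out


def run_replication(scenario: Scenario, seed: int,
                    methods: Sequence[str] = ALL_METHODS,
                    ssvs_prior=None, ssvs_config=None) -> ReplicationResult:
    dataset = generate(scenario, seed)
    data = standardize(dataset.X, dataset.y)
    fits = fit_methods(data, methods, seed=seed, ssvs_prior=ssvs_prior,
                       ssvs_config=ssvs_config)
    return ReplicationResult(scenario.name, seed, fits)


def inclusion_rates(results: Sequence[ReplicationResult],
                    effect_class: Sequence[str]) -> pd.DataFrame:
    """Percent of (predictor, replication) cells selected, by method and class."""
    if not results:
        raise ValueError("no replications")
    classes = [c for c in EFFECT_CLASS_ORDER if c in set(effect_class)]
    cls_idx = {c: np.array([i for i, e in enumerate(effect_class) if e == c])
               for c in classes}
    methods = list(results[0].methods)
    table = pd.DataFrame(index=methods, columns=classes, dtype=float)
    for method in methods:
        sel = np.vstack([r.methods[method].support for r in results])
        for c in classes:
            table.loc[method, c] = 100.0 * sel[:, cls_idx[c]].mean()
    return table


def coefficient_summary(results: Sequence[ReplicationResult],
                        effect_class: Sequence[str]) -> pd.DataFrame:
    """Estimate mean, bias, and 95% spread per method and effect class.

    Bias is benchmarked against the raw generating coefficients
    (0 / .3 / .9 / 1.5); relative bias is undefined for the null class and
    reported as NaN there.
    """
    classes = [c for c in EFFECT_CLASS_ORDER if c in set(effect_class)]
    cls_idx = {c: np.array([i for i, e in enumerate(effect_class) if e == c])
               for c in classes}
    rows = {}
    for method in results[0].methods:
        est = np.vstack([r.methods[method].estimates for r in results])
        for c in classes:
            vals = est[:, cls_idx[c]].ravel()
            true = CLASS_TRUE_VALUE[c]
            mean = vals.mean()
            rows[(method, c)] = {
                "mean_estimate": mean,
                "abs_bias": mean - true,
                "rel_bias_pct": 100.0 * (mean - true) / true if true else np.nan,
                "q025": np.percentile(vals, 2.5),
                "q975": np.percentile(vals, 97.5),
            }
    frame = pd.DataFrame(rows).T
    frame.index.names = ["method", "effect_class"]
    return frame


def run_condition(scenario: Scenario, methods: Sequence[str] = ALL_METHODS,
                  reps: int = 100, base_seed: int = 0,
                  ssvs_prior=None, ssvs_config=None) -> ConditionSummary:
    """Generate, fit, and aggregate ``reps`` replications of one condition.

    Replication r uses seed ``base_seed + r`` (r = 1..reps) for both the data
    and the chain, so the whole summary is reproducible from ``base_seed``.
    A failing replication is logged and dropped, and counted in
    ``n_failures``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; valid: {ALL_METHODS}")
    from .simulate import effect_classes, true_beta
    effect_class = effect_classes(true_beta(scenario))
    truth = true_beta(scenario) != 0

    results, failures = [], 0
    for r in range(1, reps + 1):
        try:
            results.append(run_replication(scenario, base_seed + r, methods,
                                           ssvs_prior, ssvs_config))
        except Exception:
            failures += 1
            log.exception("replication %d of %s failed; dropped", r, scenario.name)
    if not results:
        raise RuntimeError(f"all {reps} replications of {scenario.name} failed")

    auc, model_size = {}, {}
    for method in results[0].methods:
        sizes = [int(r.methods[method].support.sum()) for r in results]
        model_size[method] = float(np.mean(sizes))
        if results[0].methods[method].scores is not None:
            auc[method] = float(np.mean([
                roc_auc(r.methods[method].scores, truth) for r in results]))

    return ConditionSummary(
        scenario=scenario,
        reps=len(results),
        n_failures=failures,
        inclusion=inclusion_rates(results, effect_class),
        coefficients=coefficient_summary(results, effect_class),
        auc=auc,
        model_size=model_size,
    )
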