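"""Confounding-function bias analysis: de-bias the outcome, then refit.

The confounding function q(x; alpha) specifies the assumed average difference
in the potential outcome Y(x) between the exposed and unexposed groups at the
same covariate values -- the part of the group contrast that is confounding
rather than effect.  Subtracting q(X_i; alpha) * (1 - Pr(X = X_i | C_i)) from
each observed outcome removes that confounding under the assumed function,
and the exposure effect is re-estimated from the adjusted outcome:

    Y_adj_i = Y_i - q(X_i; alpha) * (1 - p_i_obs).

The built-in *one-sided* function is the constant q = alpha, appropriate when
the confounding is assumed equal in both exposure groups.  alpha can be given
in outcome units or as a signed share ``r2_alpha`` of the unexplained outcome
variance, mapped through alpha = sign * sqrt(|r2_alpha| * sigma2_naive).

The adjustment is linear in alpha, so the estimate traces a straight line
``naive - slope * alpha``; the tipping point is available in closed form as
``alpha_0 = naive / slope``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .regression import Dataset, NaiveFit, fit_naive
from .results import AdjustedResult, BenchmarkEntry, make_adjusted

__all__ = [
    "ConfoundingFunctionParams",
    "propensity",
    "adjust_outcome",
    "sensitivity_curve",
    "adjustment_slope",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-6

ConfoundingFn = Callable[[np.ndarray, np.ndarray, float], np.ndarray]


def one_sided(x: np.ndarray, covariates: np.ndarray, alpha: float) -> np.ndarray:
    """One-sided confounding function: the exposed group's potential outcomes sit
    ``alpha`` above the unexposed group's in *both* arms.

    Returned as the expected difference between the observed group and the
    counterfactual group, so it is ``+alpha`` for exposed rows and ``-alpha``
    for unexposed rows; the adjustment then subtracts ``alpha * (1 - p_i)``
    from the exposed and adds ``alpha * p_i`` to the unexposed.
    """
    return np.where(np.asarray(x) == 1, alpha, -alpha)


@dataclass(frozen=True)
class ConfoundingFunctionParams:
    """Either a raw confounding amount (outcome units) or a signed variance share.

    ``r2_alpha`` is the share of unexplained outcome variance attributed to
    confounding; its sign gives the bias direction.  Exactly one of
    ``alpha_raw`` / ``r2_alpha`` is supplied; the other is derived from the
    naive residual variance via alpha = sign * sqrt(|r2_alpha| * sigma2).
    """

    alpha_raw: float | None = None
    r2_alpha: float | None = None

    def __post_init__(self) -> None:
        if (self.alpha_raw is None) == (self.r2_alpha is None):
            raise ValueError("supply exactly one of alpha_raw or r2_alpha")
        if self.r2_alpha is not None and abs(self.r2_alpha) >= 1:
            raise ValueError("|r2_alpha| must be < 1")

    def resolve_alpha(self, sigma2_naive: float) -> float:
        if self.alpha_raw is not None:
            return self.alpha_raw
        r2 = self.r2_alpha
        return math.copysign(math.sqrt(abs(r2) * sigma2_naive), r2)

    def resolve_r2(self, sigma2_naive: float) -> float:
        if self.r2_alpha is not None:
            return self.r2_alpha
        a = self.alpha_raw
        return math.copysign(a**2 / sigma2_naive, a)


def propensity(data: Dataset, model: str = "logistic") -> np.ndarray:
    """Estimated Pr(X = 1 | C) for every row, clipped away from 0 and 1.

    Logistic regression by default; ``model='probit'`` switches the link.
    """
    import warnings

    M = np.column_stack([np.ones(data.n), data.covariates])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        names = ["(intercept)", *data.covariate_names]
        dup = [
            names[j] for j in range(M.shape[1])
            if np.linalg.matrix_rank(np.delete(M, j, axis=1)) == np.linalg.matrix_rank(M)
        ]
        raise ValueError(f"collinear covariates in the propensity model: {dup}")
    cls = sm.Logit if model == "logistic" else sm.Probit
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = cls(data.x, M).fit(disp=0, warn_convergence=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(f"perfect separation in the propensity model: {exc}") from exc
    p = np.asarray(res.predict())
    n_clipped = int(np.sum((p < _CLIP) | (p > 1 - _CLIP)))
    if n_clipped:
        logger.info("propensity: clipped %d fitted probabilities to [%g, %g]", n_clipped, _CLIP, 1 - _CLIP)
    return np.clip(p, _CLIP, 1 - _CLIP)


def adjust_outcome(
    data: Dataset,
    propensity_scores: np.ndarray,
    alpha_raw: float,
    confounding_fn: ConfoundingFn = one_sided,
) -> np.ndarray:
    """De-biased outcome Y_adj_i = Y_i - q(X_i; alpha) * (1 - Pr(X = X_i | C_i))."""
    p = np.asarray(propensity_scores, dtype=float)
    if len(p) != data.n:
        raise ValueError("propensity length mismatch")
    p_obs = np.where(data.x == 1, p, 1 - p)
    q = np.asarray(confounding_fn(data.x, data.covariates, alpha_raw), dtype=float)
    y_adj = data.y - q * (1 - p_obs)
    bad = np.flatnonzero(~np.isfinite(y_adj))
    if bad.size:
        raise ValueError(f"non-finite adjusted outcome at rows {bad[:5].tolist()}")
    return y_adj


def _refit(data: Dataset, y_adj: np.ndarray, conf_level: float) -> AdjustedResult:
    adj_data = Dataset(
        y=y_adj,
        x=data.x,
        covariates=data.covariates,
        covariate_names=data.covariate_names,
        outcome_name=data.outcome_name,
        exposure_name=data.exposure_name,
    )
    fit = fit_naive(adj_data, alpha=1 - conf_level)
    lo, hi = fit.ci(conf_level)
    return AdjustedResult(
        estimate=fit.estimate,
        se=fit.se,
        t_value=fit.t_value,
        df=fit.df,
        ci_low=lo,
        ci_high=hi,
        conf_level=conf_level,
        method="confounding_function",
        params={},
    )


def sensitivity_curve(
    data: Dataset,
    r2_grid: Sequence[float],
    conf_level: float = 0.95,
    confounding_fn: ConfoundingFn = one_sided,
    propensity_model: str = "logistic",
) -> tuple[list[AdjustedResult], list[BenchmarkEntry]]:
    """Bias-adjusted estimates over a grid of signed variance shares r2_alpha.

    Returns one :class:`AdjustedResult` per grid value (the r2 = 0 entry
    reproduces the naive fit exactly) plus benchmark markers: each measured
    covariate's partial R^2 with the outcome, to be read as plausible
    magnitudes of |r2_alpha| in both directions.
    """
    naive = fit_naive(data, alpha=1 - conf_level)
    p = propensity(data, model=propensity_model)
    results = []
    for r2 in r2_grid:
        params = ConfoundingFunctionParams(r2_alpha=float(r2))
        alpha_raw = params.resolve_alpha(naive.sigma2)
        if r2 == 0:
            res = _refit(data, data.y, conf_level)
        else:
            res = _refit(data, adjust_outcome(data, p, alpha_raw, confounding_fn), conf_level)
        res.params.update({"r2_alpha": float(r2), "alpha_raw": float(alpha_raw)})
        results.append(res)
    benchmarks = [
        BenchmarkEntry(
            name=str(name),
            label=f"+/- {name}",
            scale="r2_alpha",
            values={"r2_alpha_magnitude": float(row["partial_r2_y"])},
            strength=float(row["partial_r2_y"]),
        )
        for name, row in (naive.covariates.iterrows() if naive.covariates is not None else [])
    ]
    benchmarks.sort(key=lambda e: e.strength, reverse=True)
    return results, benchmarks


def adjustment_slope(
    data: Dataset,
    propensity_scores: np.ndarray | None = None,
    confounding_fn: ConfoundingFn = one_sided,
) -> float:
    """Slope of the (linear) mapping alpha -> naive_estimate - estimate(alpha).

    The one-sided adjustment is linear in alpha, so two fits determine the
    whole curve; the null tipping point is alpha_0 = naive / slope.
    """
    if propensity_scores is None:
        propensity_scores = propensity(data)
    naive = fit_naive(data)
    at_one = _refit(data, adjust_outcome(data, propensity_scores, 1.0, confounding_fn), 0.95)
    return naive.estimate - at_one.estimate
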