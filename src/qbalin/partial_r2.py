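"""Partial-R^2 bias analysis: omitted-variable adjustment, robustness values, benchmarks.

The unmeasured confounder U is parameterised by two partial R^2 values:

* ``r2_xu`` = R^2 of X with U given C -- the share of exposure variance left
  unexplained by measured covariates that U would explain;
* ``r2_yu`` = R^2 of Y with U given X and C -- the share of residual outcome
  variance that U would explain.

For a *real* omitted regressor these formulas are exact sample identities:
plugging U's sample partial R^2 values into :func:`adjust` reproduces the
coefficient and standard error of the regression that includes U, to machine
precision.  That identity is the backbone of this module's test suite.

The robustness value (RV) summarises the whole sensitivity surface in one
number: the minimal equal strength ``r2_xu = r2_yu`` that would remove a
fraction ``q`` of the naive estimate (or, with a significance level supplied,
reduce its t statistic to the critical value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import Dataset, NaiveFit, fit_naive
from .results import AdjustedResult, BenchmarkEntry, ContourSet, GridSpec, extract_levels, make_adjusted

__all__ = [
    "PartialR2Params",
    "bias_magnitude",
    "adjust",
    "robustness_value",
    "extreme_confounder_bound",
    "benchmark_partial_r2",
    "contour_grid",
]

_CAP = 1 - 1e-6  # benchmark proportions are capped strictly below 1


@dataclass(frozen=True)
class PartialR2Params:
    """Bias parameters on the partial-R^2 scale."""

    r2_xu: float
    r2_yu: float
    direction: str = "toward-null"  # or "away-from-null"

    def __post_init__(self) -> None:
        if not 0 <= self.r2_xu < 1:
            raise ValueError("r2_xu must be in [0, 1); 1 means X fully explained by U")
        if not 0 <= self.r2_yu <= 1:
            raise ValueError("r2_yu must be in [0, 1]")
        if self.direction not in ("toward-null", "away-from-null"):
            raise ValueError("direction must be 'toward-null' or 'away-from-null'")


def bias_magnitude(fit: NaiveFit, params: PartialR2Params) -> float:
    """Absolute bias (outcome units) implied by the partial-R^2 parameters.

    bias = se * sqrt(df) * sqrt(r2_yu * r2_xu / (1 - r2_xu))
    """
    if params.r2_xu >= 1:
        raise ValueError("exposure fully explained (r2_xu = 1): bias undefined")
    return (
        fit.se
        * math.sqrt(fit.df)
        * math.sqrt(params.r2_yu * params.r2_xu / (1 - params.r2_xu))
    )


def _adjusted_se(fit: NaiveFit, params: PartialR2Params) -> float:
    return (
        fit.se
        * math.sqrt((1 - params.r2_yu) / (1 - params.r2_xu))
        * math.sqrt(fit.df / (fit.df - 1))
    )


def adjust(
    fit: NaiveFit, params: PartialR2Params, conf_level: float | None = None
) -> AdjustedResult:
    """Bias-adjusted estimate, SE and Student-t interval at df - 1.

    The adjustment moves the naive estimate by the bias magnitude toward or
    away from the null per ``params.direction``; the SE contracts with
    ``r2_yu`` (U explains outcome noise) and inflates with ``r2_xu`` (U
    absorbs exposure variation).
    """
    if fit.df <= 1:
        raise ValueError("need df > 1 for the adjusted fit")
    level = fit.conf_level if conf_level is None else conf_level
    sign = 1.0 if fit.estimate >= 0 else -1.0
    bias = bias_magnitude(fit, params)
    if params.direction == "toward-null":
        estimate = fit.estimate - sign * bias
    else:
        estimate = fit.estimate + sign * bias
    se = _adjusted_se(fit, params)
    return make_adjusted(
        estimate,
        se,
        fit.df - 1,
        level,
        "partial_r2",
        {"r2_xu": params.r2_xu, "r2_yu": params.r2_yu, "direction": params.direction},
    )


def robustness_value(fit: NaiveFit, q: float = 1.0, alpha: float | None = None) -> float:
    """Minimal equal partial R^2 of U with X and Y that removes q of the effect.

    Without ``alpha`` the criterion is the point estimate: the returned RV is
    the equal strength ``r2_xu = r2_yu`` at which the adjusted estimate equals
    ``(1 - q)`` times the naive estimate.  With ``alpha`` the criterion is
    statistical significance of the adjusted t statistic at that level
    (critical t taken at df - 1).  Returns a proportion in [0, 1).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if fit.df <= 1:
        raise ValueError("need df > 1")
    f = abs(fit.t_value) / math.sqrt(fit.df)
    if alpha is None:
        fq = q * f
    else:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        f_star = stats.t.ppf(1 - alpha / 2, fit.df - 1) / math.sqrt(fit.df - 1)
        fq = q * f - f_star
        if fq <= 0:
            return 0.0
    return 0.5 * (math.sqrt(fq**4 + 4 * fq**2) - fq**2)


def extreme_confounder_bound(fit: NaiveFit, q: float = 1.0) -> float:
    """Smallest r2_xu removing q of the estimate when U explains all residual Y variance.

    Worst case ``r2_yu = 1``; closed form r2_xu = f_q^2 / (1 + f_q^2) with
    f_q = q |t| / sqrt(df).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    fq = q * abs(fit.t_value) / math.sqrt(fit.df)
    return fq**2 / (1 + fq**2)


def benchmark_partial_r2(
    data: Dataset,
    fit: NaiveFit | None = None,
    multipliers: tuple[float, ...] = (1.0,),
) -> list[BenchmarkEntry]:
    """Informal benchmark bounds from each measured covariate's partial R^2 pair.

    For covariate j and multiplier k the entry carries
    ``r2_xu = k * R^2_{X~Cj|C-j}`` and ``r2_yu = k * R^2_{Y~Cj|X,C-j}``
    (capped below 1).  Entries are sorted by the product r2_xu * r2_yu, so the
    first multiplier-1 entry is the strongest measured covariate.  These
    bounds do not adjust for the omission of U itself.
    """
    if fit is None:
        fit = fit_naive(data)
    if fit.covariates is None:
        raise ValueError("benchmarking requires data (summary-only fit supplied)")
    entries: list[BenchmarkEntry] = []
    for name, row in fit.covariates.iterrows():
        if not np.isfinite(row["partial_r2_x"]) or not np.isfinite(row["partial_r2_y"]):
            import warnings

            warnings.warn(f"covariate '{name}' is degenerate (constant?); skipped")
            continue
        for k in multipliers:
            r2x = min(k * row["partial_r2_x"], _CAP)
            r2y = min(k * row["partial_r2_y"], _CAP)
            entries.append(
                BenchmarkEntry(
                    name=str(name),
                    label=f"{k:g}x {name}",
                    scale="partial_r2",
                    values={"r2_xu": float(r2x), "r2_yu": float(r2y)},
                    strength=float(r2x * r2y),
                )
            )
    entries.sort(key=lambda e: e.strength, reverse=True)
    return entries


def contour_grid(
    fit: NaiveFit,
    target: str = "estimate",
    grid: GridSpec | None = None,
    alpha: float = 0.05,
) -> ContourSet:
    """Adjusted estimate (or t value) over a partial-R^2 grid, with level sets.

    The surface assumes bias toward the null (the adjusted estimate continues
    linearly through zero).  Extracted levels: the null estimate for
    ``target='estimate'``; the critical t at ``alpha`` (df - 1) for
    ``target='t_value'``.
    """
    if target not in ("estimate", "t_value"):
        raise ValueError("target must be 'estimate' or 't_value'")
    grid = grid or GridSpec()
    xs, ys = grid.axes()
    xx, yy = np.meshgrid(xs, ys)
    sign = 1.0 if fit.estimate >= 0 else -1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = fit.se * np.sqrt(fit.df) * np.sqrt(yy * xx / (1 - xx))
        est = fit.estimate - sign * bias
        if target == "estimate":
            values = est
            level = 0.0
            tag = "null"
        else:
            se = fit.se * np.sqrt((1 - yy) / (1 - xx)) * math.sqrt(fit.df / (fit.df - 1))
            values = est / se
            level = sign * stats.t.ppf(1 - alpha / 2, fit.df - 1)
            tag = "critical_t"
    cs = ContourSet(
        x_name="r2_xu",
        y_name="r2_yu",
        x=xs,
        y=ys,
        values=values,
        target=target,
    )
    cs.levels[tag] = extract_levels(xs, ys, values, level)
    if target == "estimate" and grid.x_min == 0.0 and grid.y_min == 0.0:
        # the naive level set is exactly the two axes (bias = 0 iff r2_xu*r2_yu = 0)
        cs.levels["naive"] = [
            np.column_stack([xs, np.zeros_like(xs)]),
            np.column_stack([np.zeros_like(ys), ys]),
        ]
    return cs
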