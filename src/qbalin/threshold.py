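"""Percent bias to invalidate/sustain an inference and the impact threshold (ITCV).

These statistics ask how much unmeasured confounding would change the
*statistical significance* of the naive exposure effect:

* **percent bias** -- the share of the naive estimate that confounding must
  account for before the p-value crosses the significance level (or, for an
  insignificant estimate, the growth needed to reach significance);
* **impact threshold for a confounding variable (ITCV)** -- the minimal
  product of partial correlations of U with exposure and outcome (given C)
  that makes the estimate statistically insignificant; the equal-correlation
  value sqrt(ITCV) is the threshold each correlation must exceed when both
  are equal.

The module also exposes :func:`adjust_estimate`, the exact partial-correlation
update: for a real omitted regressor with sample partial correlations
``(r_xu, r_yu)`` it reproduces the coefficient of the regression including U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .regression import Dataset, NaiveFit, fit_naive, partial_stats
from .results import AdjustedResult, BenchmarkEntry, make_adjusted

__all__ = [
    "CorrelationParams",
    "percent_bias",
    "impact_threshold",
    "benchmark_correlations",
    "adjust_estimate",
]


@dataclass(frozen=True)
class CorrelationParams:
    """Partial correlations of the unmeasured confounder with X and with Y, given C."""

    r_xu: float
    r_yu: float

    def __post_init__(self) -> None:
        if not (-1 < self.r_xu < 1 and -1 < self.r_yu < 1):
            raise ValueError("partial correlations must be in (-1, 1)")

    @property
    def impact(self) -> float:
        return self.r_xu * self.r_yu


def percent_bias(fit: NaiveFit, alpha: float = 0.05) -> tuple[float, str]:
    """Percent of the naive estimate that bias must explain to flip significance.

    If the naive estimate is significant at ``alpha`` the mode is
    ``"invalidate"``: returns 100*(1 - t_crit*se/|estimate|), the minimum
    share of the estimate that confounding must remove for insignificance.
    Otherwise the mode is ``"sustain"``: 100*(t_crit*se/|estimate| - 1), the
    growth needed to reach significance.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_crit = fit.critical_t(alpha)
    if abs(fit.t_value) > t_crit:
        return 100.0 * (1 - t_crit * fit.se / abs(fit.estimate)), "invalidate"
    if fit.estimate == 0:
        raise ValueError("percent bias undefined in sustain mode for a null estimate")
    return 100.0 * (t_crit * fit.se / abs(fit.estimate) - 1), "sustain"


def impact_threshold(fit: NaiveFit, alpha: float = 0.05) -> tuple[float, float]:
    """ITCV and the equal-correlation value sqrt(max(ITCV, 0)).

    With r = t/sqrt(t^2+df) the partial correlation of exposure and outcome
    and r# the correlation matching the critical t (sign matching r), the
    threshold is (|r| - r#)/(1 - r#): the product r_xu*r_yu at which the
    adjusted estimate sits exactly at the significance boundary.
    """
    t_crit = fit.critical_t(alpha)
    r = abs(fit.t_value) / math.sqrt(fit.t_value**2 + fit.df)
    r_sharp = t_crit / math.sqrt(t_crit**2 + fit.df)
    itcv = (r - r_sharp) / (1 - r_sharp)
    return itcv, math.sqrt(max(itcv, 0.0))


def adjust_estimate(
    fit: NaiveFit, params: CorrelationParams, conf_level: float | None = None
) -> AdjustedResult:
    """Exposure effect after partialling out a confounder with the given correlations.

    Applies the partial-correlation recursion
    r_adj = (r - r_xu*r_yu) / sqrt((1-r_xu^2)(1-r_yu^2)) and rescales the
    coefficient by the residual-SD ratio sqrt((1-r_yu^2)/(1-r_xu^2)); for a
    real omitted regressor both steps are exact sample identities.
    """
    if fit.df <= 1:
        raise ValueError("need df > 1")
    level = fit.conf_level if conf_level is None else conf_level
    r = fit.partial_corr_exposure
    denom = math.sqrt((1 - params.r_xu**2) * (1 - params.r_yu**2))
    r_adj = (r - params.impact) / denom
    if not -1 < r_adj < 1:
        raise ValueError("adjusted partial correlation outside (-1, 1); parameters inconsistent")
    scale = math.sqrt((1 - params.r_yu**2) / (1 - params.r_xu**2))
    estimate = fit.estimate * (r_adj / r) * scale if r != 0 else 0.0
    df_adj = fit.df - 1
    # back out the SE from the adjusted t statistic implied by r_adj at df - 1
    t_adj = r_adj * math.sqrt(df_adj) / math.sqrt(1 - r_adj**2)
    se = abs(estimate / t_adj) if t_adj != 0 else fit.se * scale
    return make_adjusted(
        estimate,
        se,
        df_adj,
        level,
        "threshold",
        {"r_xu": params.r_xu, "r_yu": params.r_yu},
    )


def benchmark_correlations(data: Dataset) -> list[BenchmarkEntry]:
    """Each covariate's partial correlations with X and Y given the others.

    The Y-side correlation conditions on the remaining covariates only (not
    the exposure), matching the definition of the confounder's own parameter
    r_{Y~U|C}.  Entries are sorted by |impact| = |r_x * r_y| descending.
    """
    if data.n_covariates == 0:
        return []
    entries = []
    import warnings

    for j, name in enumerate(data.covariate_names):
        others = np.delete(data.covariates, j, axis=1)
        cj = data.covariates[:, [j]]
        M = np.column_stack([cj, others])
        if np.std(cj) == 0:
            warnings.warn(f"covariate '{name}' is constant; skipped")
            continue
        r_x = float(partial_stats(data.x, M)["partial_corr"].iloc[0])
        r_y = float(partial_stats(data.y, M)["partial_corr"].iloc[0])
        note = "informal benchmark"
        if abs(r_x) > 0.99:
            note += "; near-collinear with exposure"
            warnings.warn(f"covariate '{name}' nearly collinear with exposure (r = {r_x:.3f})")
        entries.append(
            BenchmarkEntry(
                name=name,
                label=f"1x {name}",
                scale="correlation",
                values={"r_xu": r_x, "r_yu": r_y, "impact": r_x * r_y},
                strength=abs(r_x * r_y),
                note=note,
            )
        )
    entries.sort(key=lambda e: e.strength, reverse=True)
    return entries


def narrative_report(fit: NaiveFit, alpha: float = 0.05) -> str:
    """Plain-text narrative mirroring the threshold statistics."""
    pb, mode = percent_bias(fit, alpha)
    itcv, rr = impact_threshold(fit, alpha)
    if mode == "invalidate":
        head = (
            f"In order for the exposure effect to be statistically insignificant at the "
            f"{100 * alpha:g}% level, unmeasured confounding would need to account for at least "
            f"{pb:.2f}% of the naive estimate ({fit.estimate:.4g})."
        )
    else:
        head = (
            f"The naive estimate is not statistically significant at the {100 * alpha:g}% level; "
            f"its magnitude would need to grow by {pb:.2f}% to reach significance."
        )
    tail = (
        f" The impact threshold for a confounding variable is {itcv:.4f}: the partial "
        f"correlations of the confounder with outcome and exposure must both exceed {rr:.4f} "
        f"(when equal) to render the estimate statistically insignificant."
    )
    return head + tail
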