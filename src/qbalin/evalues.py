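"""E-values: worst-case risk-ratio strength of confounding that explains an effect.

An unmeasured confounder U with risk-ratio associations ``rr_xu`` (exposure
with U, given C) and ``rr_uy`` (U with outcome, given C) can shift an observed
risk ratio by at most the *bounding factor*

    B = rr_xu * rr_uy / (rr_xu + rr_uy - 1).

The E-value is the minimal equal strength ``rr_xu = rr_uy`` at which B reaches
the observed risk ratio, i.e. at which confounding alone could move the
estimate to the null:

    E(rr) = rr + sqrt(rr * (rr - 1))   for rr >= 1 (invert rr < 1 first).

Linear-regression effects enter on the risk-ratio scale through the
standardized mean difference d = estimate / SD(Y) and the conventional
conversion RR ~= exp(0.91 * d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import Dataset, NaiveFit, fit_naive
from .results import BenchmarkEntry

__all__ = [
    "RiskRatioParams",
    "EffectOnRRScale",
    "evalue",
    "rr_from_linear",
    "evalue_report",
    "bias_factor_contour",
    "benchmark_evalues",
    "bounding_factor",
    "prevalence_bias_factor",
]

D_TO_RR = 0.91  # conventional constant for exp(k*d) conversion of a mean difference


@dataclass(frozen=True)
class RiskRatioParams:
    """Confounder strengths as risk ratios, oriented to be >= 1."""

    rr_xu: float
    rr_uy: float

    def __post_init__(self) -> None:
        if self.rr_xu < 1 or self.rr_uy < 1:
            raise ValueError("risk-ratio parameters must be >= 1 after orientation")


def bounding_factor(rr_xu: float, rr_uy: float) -> float:
    """Maximal multiplicative bias B = rr_xu*rr_uy/(rr_xu+rr_uy-1) (always >= 1)."""
    if rr_xu < 1 or rr_uy < 1:
        raise ValueError("risk ratios must be >= 1 after orientation")
    return rr_xu * rr_uy / (rr_xu + rr_uy - 1)


@dataclass(frozen=True)
class EffectOnRRScale:
    """An exposure effect and CI expressed as risk ratios."""

    rr_point: float
    rr_ci_low: float
    rr_ci_high: float
    provenance: str = "direct"  # or "converted-from-d"
    d: float | None = None
    se_d: float | None = None

    def __post_init__(self) -> None:
        if min(self.rr_point, self.rr_ci_low, self.rr_ci_high) <= 0:
            raise ValueError("risk ratios must be positive")
        if not self.rr_ci_low <= self.rr_point <= self.rr_ci_high:
            raise ValueError("rr_ci_low <= rr_point <= rr_ci_high required")


def evalue(rr: float) -> float:
    """E-value of a risk ratio: E = rr' + sqrt(rr'(rr'-1)) with rr' = max(rr, 1/rr)."""
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    rrp = max(rr, 1 / rr)
    return rrp + math.sqrt(rrp * (rrp - 1))


def rr_from_linear(
    fit: NaiveFit,
    sd_outcome: float | None = None,
    d: float | None = None,
    se_d: float | None = None,
    conf_level: float = 0.95,
) -> EffectOnRRScale:
    """Convert a linear-regression effect to the risk-ratio scale.

    Either supply the outcome SD (then d = estimate/SD, se_d = se/SD) or a
    standardized mean difference ``d`` with its ``se_d`` directly.  The CI on
    the d scale uses the normal quantile, matching the large-sample convention
    of the conversion itself.
    """
    if d is None:
        if sd_outcome is None or sd_outcome <= 0:
            raise ValueError("sd_outcome must be positive (or supply d and se_d)")
        d = fit.estimate / sd_outcome
        se_d = fit.se / sd_outcome
    elif se_d is None:
        raise ValueError("se_d required when d is supplied")
    z = stats.norm.ppf((1 + conf_level) / 2)
    return EffectOnRRScale(
        rr_point=math.exp(D_TO_RR * d),
        rr_ci_low=math.exp(D_TO_RR * (d - z * se_d)),
        rr_ci_high=math.exp(D_TO_RR * (d + z * se_d)),
        provenance="converted-from-d",
        d=d,
        se_d=se_d,
    )


def evalue_report(effect: EffectOnRRScale, true_rr: float = 1.0) -> tuple[float, float]:
    """E-values for the point estimate and for the CI limit, relative to ``true_rr``.

    The point E-value answers: how strong (equal risk ratios with exposure and
    outcome) must U be for the true effect to be ``true_rr``?  The CI E-value
    uses the CI limit closer to ``true_rr``; it is 1 when the CI covers
    ``true_rr``.
    """
    if true_rr <= 0:
        raise ValueError("true_rr must be positive")
    e_point = evalue(effect.rr_point / true_rr)
    if effect.rr_ci_low <= true_rr <= effect.rr_ci_high:
        e_ci = 1.0
    elif effect.rr_ci_low > true_rr:
        e_ci = evalue(effect.rr_ci_low / true_rr)
    else:
        e_ci = evalue(effect.rr_ci_high / true_rr)
    return e_point, e_ci


def bias_factor_contour(
    effect: EffectOnRRScale,
    true_rr: float = 1.0,
    rr_xu_max: float = 8.0,
    resolution: int = 201,
) -> dict:
    """The locus of (rr_xu, rr_uy) whose bounding factor equals the observed ratio.

    Solving B(rr_xu, rr_uy) = B_obs gives rr_uy = B_obs*(rr_xu - 1)/(rr_xu -
    B_obs), defined for rr_xu > B_obs; both coordinates tend to B_obs as the
    other grows (the asymptotes) and meet at the E-value on the diagonal.
    """
    ratio = effect.rr_point / true_rr
    ratio = max(ratio, 1 / ratio)
    if ratio <= 1:
        return {
            "observed_ratio": ratio,
            "rr_xu": np.array([]),
            "rr_uy": np.array([]),
            "asymptote": ratio,
            "evalue": 1.0,
            "note": "observed ratio <= 1: no confounding needed, contour empty",
        }
    e = evalue(ratio)
    hi = max(rr_xu_max, 2 * e)
    lo = ratio * (hi - 1) / (hi - ratio)  # symmetric image of hi, so the curve spans both arms
    xs = np.linspace(lo, hi, resolution)
    with np.errstate(divide="ignore"):
        ys = ratio * (xs - 1) / (xs - ratio)
    return {
        "observed_ratio": ratio,
        "rr_xu": xs,
        "rr_uy": ys,
        "asymptote": ratio,
        "evalue": e,
        "note": "",
    }


def benchmark_evalues(
    data: Dataset, conf_level: float = 0.95, alpha: float = 0.05
) -> list[BenchmarkEntry]:
    """Benchmark E-values by omitting one measured covariate at a time.

    Each entry is the E-value of the ratio of the leave-one-out naive effect
    to the full naive effect on the risk-ratio scale (both converted with the
    observed outcome SD), i.e. the confounding strength a covariate's omission
    actually exerts.
    """
    full = fit_naive(data, alpha=alpha)
    sd_y = float(np.std(data.y, ddof=1))
    rr_full = rr_from_linear(full, sd_outcome=sd_y, conf_level=conf_level).rr_point
    entries = []
    for name in data.covariate_names:
        sub = fit_naive(data.drop_covariate(name), alpha=alpha)
        rr_sub = rr_from_linear(sub, sd_outcome=sd_y, conf_level=conf_level).rr_point
        ratio = rr_sub / rr_full
        e = evalue(ratio)
        entries.append(
            BenchmarkEntry(
                name=name,
                label=f"omit {name}",
                scale="evalue",
                values={"rr_ratio": float(ratio), "benchmark_evalue": float(e)},
                strength=float(e),
                note="leave-one-out vs full naive fit, RR scale",
            )
        )
    entries.sort(key=lambda x: x.strength, reverse=True)
    return entries


def prevalence_bias_factor(rr_uy: float, p1: float, p0: float) -> float:
    """Bias factor of a binary confounder with known arm prevalences.

    For U with outcome risk ratio ``rr_uy`` and prevalence ``p1`` among the
    exposed and ``p0`` among the unexposed, confounding multiplies the
    observed risk ratio by (1+(rr_uy-1)p1) / (1+(rr_uy-1)p0).  Used for
    prevalence-informed adjustment (in contrast to the worst-case bounding
    factor).
    """
    if rr_uy <= 0:
        raise ValueError("rr_uy must be positive")
    for p in (p1, p0):
        if not 0 <= p <= 1:
            raise ValueError("prevalences must be in [0, 1]")
    return (1 + (rr_uy - 1) * p1) / (1 + (rr_uy - 1) * p0)
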