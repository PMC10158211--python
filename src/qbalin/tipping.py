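"""Cross-method tipping-point solving and the comparative benchmark report.

A *tipping point* is the confounder strength at which a study conclusion
changes: the bias-adjusted estimate reaches the null, or the adjusted
confidence interval starts to include it.  Two-parameter methods are searched
along their equal-parameter diagonal, so every method reduces to a monotone
scalar path and a one-dimensional root-find.

The comparative report evaluates every selected method at half, once and
twice the strength of the strongest measured covariate, in both bias
directions -- the standard benchmark-multiple table for judging whether a
plausible unmeasured confounder could overturn the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from . import confounding_function as cf
from . import partial_r2 as pr2
from . import simulation as sim
from . import threshold as thr
from .regression import Dataset, NaiveFit, fit_naive
from .results import AdjustedResult, TippingPoint

__all__ = [
    "solve_tipping",
    "partial_r2_diagonal",
    "threshold_diagonal",
    "confounding_function_path",
    "simulation_diagonal",
    "comparative_report",
    "ComparativeReport",
]

Path = Callable[[float], float]


def solve_tipping(
    evaluate: Path,
    criterion: str = "null-estimate",
    interval: tuple[float, float] = (0.0, 1.0),
    method: str = "",
    tolerance: float = 1e-8,
    stochastic: bool = False,
    n_grid: int = 21,
    mc_se: float | None = None,
    alpha: float | None = None,
) -> TippingPoint:
    """Root of a monotone criterion path, with a self-verification pass.

    ``evaluate(s)`` must return the criterion value at path position ``s``
    (adjusted estimate for ``null-estimate``; CI margin or |t| - t_crit for
    ``significance``), crossing zero at the tipping point.  Closed-form paths
    are bisected to ``tolerance``; stochastic paths are bracketed on a grid of
    ``n_grid`` points and linearly interpolated, verified to 3 * ``mc_se``.
    """
    lo, hi = interval
    v_lo = evaluate(lo)
    if v_lo <= 0:
        locus = lo  # criterion already met at the start of the path
        residual = v_lo
        tol = tolerance if not stochastic else 3 * (mc_se or 0.0)
        return TippingPoint(
            method=method, criterion=criterion, value=locus, residual=float(residual),
            tolerance=tol, verified=bool(abs(residual) <= tol or residual <= 0),
            alpha=alpha, note="criterion met at path start",
        )
    if stochastic:
        if mc_se is None:
            raise ValueError("stochastic solving needs an mc_se")
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([evaluate(s) for s in grid])
        crossings = np.flatnonzero((vals[:-1] > 0) & (vals[1:] <= 0))
        if crossings.size == 0:
            raise ValueError(f"no tipping point in range {interval}")
        i = crossings[0]
        # local refinement on the bracketing segment
        seg = np.linspace(grid[i], grid[i + 1], 5)
        seg_vals = np.array([evaluate(s) for s in seg])
        j = int(np.argmin(np.abs(seg_vals)))
        locus = float(seg[j])
        residual = float(seg_vals[j])
        tol = 3 * mc_se
    else:
        from scipy.optimize import brentq

        v_hi = evaluate(hi)
        if v_lo * v_hi > 0:
            raise ValueError(f"no tipping point in range {interval}")
        locus = float(brentq(evaluate, lo, hi, xtol=tolerance * max(abs(hi), 1.0), rtol=1e-14))
        residual = float(evaluate(locus))
        tol = max(tolerance, 1e-6)
    return TippingPoint(
        method=method, criterion=criterion, value=locus, residual=residual,
        tolerance=tol, verified=bool(abs(residual) <= tol), alpha=alpha,
    )


def partial_r2_diagonal(fit: NaiveFit, criterion: str = "null-estimate", alpha: float = 0.05) -> Path:
    """Equal-parameter path s -> criterion value for the partial-R^2 method."""
    sign = 1.0 if fit.estimate >= 0 else -1.0

    def path(s: float) -> float:
        res = pr2.adjust(fit, pr2.PartialR2Params(s, s, "toward-null"))
        if criterion == "null-estimate":
            return sign * res.estimate
        return sign * res.t_value - fit.critical_t(alpha, fit.df - 1)

    return path


def threshold_diagonal(fit: NaiveFit, criterion: str = "significance", alpha: float = 0.05) -> Path:
    """Equal-correlation path s -> criterion value for the impact-threshold method."""
    sign = 1.0 if fit.estimate >= 0 else -1.0

    def path(s: float) -> float:
        try:
            res = thr.adjust_estimate(fit, thr.CorrelationParams(sign * s, s))
        except ValueError:
            # correlations this strong are inconsistent with the observed
            # partial correlation: the estimate is far past the criterion
            return -1e6
        if criterion == "null-estimate":
            return sign * res.estimate
        return sign * res.t_value - fit.critical_t(alpha)

    return path


def confounding_function_path(
    data: Dataset, criterion: str = "null-estimate", alpha: float = 0.05
) -> tuple[Path, float]:
    """Path over the raw confounding amount, plus the closed-form null tipping.

    Returns ``(path, alpha_0)`` where ``alpha_0 = naive / slope`` from the
    linearity of the adjustment in alpha.
    """
    naive = fit_naive(data, alpha=alpha)
    p = cf.propensity(data)
    slope = cf.adjustment_slope(data, p)
    sign = 1.0 if naive.estimate >= 0 else -1.0

    def path(a: float) -> float:
        y_adj = cf.adjust_outcome(data, p, a)
        res = cf._refit(data, y_adj, 1 - alpha)
        if criterion == "null-estimate":
            return sign * res.estimate
        return abs(res.t_value) - naive.critical_t(alpha)

    return path, naive.estimate / slope


def simulation_diagonal(
    data: Dataset,
    params: sim.SimulationParams,
    criterion: str = "null-estimate",
    alpha: float = 0.05,
    zeta_ratio: float = 1.0,
) -> Path:
    """Stochastic path s -> criterion value running the sampler at (s, s*zeta_ratio)."""
    from dataclasses import replace

    naive = fit_naive(data, alpha=alpha)
    sign = 1.0 if naive.estimate >= 0 else -1.0

    def path(s: float) -> float:
        p = replace(params, zeta_y=sign * s, zeta_x=s * zeta_ratio)
        res = sim.run_simulation_qba(data, p, 1 - alpha)
        if criterion == "null-estimate":
            return sign * res.estimate
        adj = res.to_adjusted()
        return sign * adj.t_value - naive.critical_t(alpha, res.df)

    return path


# ---------------------------------------------------------------------------
# comparative report
# ---------------------------------------------------------------------------

DEFAULT_METHODS = ("partial_r2", "confounding_function", "simulation", "threshold")


@dataclass
class ComparativeReport:
    """Bias-adjusted results per method at benchmark multiples in both directions."""

    naive: AdjustedResult
    fully_adjusted: AdjustedResult | None
    multipliers: tuple[float, ...]
    cells: dict[tuple[str, str, float], dict[str, Any]] = field(default_factory=dict)
    strongest: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (method, direction, mult), cell in sorted(self.cells.items()):
            rows.append({"method": method, "direction": direction, "multiplier": mult, **cell})
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            "| method | direction | multiplier | estimate [CI] / verdict |",
            "|---|---|---|---|",
        ]
        nv = self.naive
        lines.append(
            f"| naive | - | 0 | {nv.estimate:.2f} [{nv.ci_low:.2f}, {nv.ci_high:.2f}] |"
        )
        if self.fully_adjusted is not None:
            fa = self.fully_adjusted
            lines.append(
                f"| fully adjusted | - | - | {fa.estimate:.2f} [{fa.ci_low:.2f}, {fa.ci_high:.2f}] |"
            )
        for (method, direction, mult), cell in sorted(self.cells.items()):
            if "error" in cell:
                body = f"error: {cell['error']}"
            elif "estimate" in cell and cell["estimate"] is not None:
                body = f"{cell['estimate']:.2f} [{cell['ci_low']:.2f}, {cell['ci_high']:.2f}]"
            else:
                body = cell.get("verdict", "")
            lines.append(f"| {method} | {direction} | {mult:g} | {body} |")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "naive": self.naive.to_dict(),
            "fully_adjusted": self.fully_adjusted.to_dict() if self.fully_adjusted else None,
            "multipliers": list(self.multipliers),
            "strongest": self.strongest,
            "seed": self.seed,
            "cells": {
                f"{m}|{d}|{k:g}": cell for (m, d, k), cell in sorted(self.cells.items())
            },
        }


def _cell_from_adjusted(res: AdjustedResult) -> dict[str, Any]:
    return {
        "estimate": res.estimate,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "significant": res.significant,
    }


def comparative_report(
    data: Dataset,
    methods: Sequence[str] = DEFAULT_METHODS,
    multipliers: Sequence[float] = (0.5, 1.0, 2.0),
    alpha: float = 0.05,
    seed: int = 0,
    sim_params: sim.SimulationParams | None = None,
    u: np.ndarray | None = None,
) -> ComparativeReport:
    """Evaluate each method at multiples of its strongest-covariate benchmark.

    For every method the strongest measured covariate (largest product of the
    two benchmark strengths on that method's own scale) defines the reference
    confounder; its parameters are scaled by each multiplier and applied in
    both bias directions.  The threshold method contributes significance
    verdicts rather than adjusted estimates.  Passing the withheld confounder
    ``u`` adds a fully-adjusted reference row.  Method errors are captured per
    cell, not raised.
    """
    unknown = set(methods) - {"partial_r2", "confounding_function", "simulation", "threshold"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    conf_level = 1 - alpha
    naive = fit_naive(data, alpha=alpha)
    lo, hi = naive.ci(conf_level)
    naive_res = AdjustedResult(
        estimate=naive.estimate, se=naive.se, t_value=naive.t_value, df=naive.df,
        ci_low=lo, ci_high=hi, conf_level=conf_level, method="naive",
    )
    full_res = None
    if u is not None:
        full_fit = fit_naive(data.with_covariate("_u", u), alpha=alpha)
        flo, fhi = full_fit.ci(conf_level)
        full_res = AdjustedResult(
            estimate=full_fit.estimate, se=full_fit.se, t_value=full_fit.t_value,
            df=full_fit.df, ci_low=flo, ci_high=fhi, conf_level=conf_level,
            method="fully_adjusted",
        )

    report = ComparativeReport(
        naive=naive_res, fully_adjusted=full_res, multipliers=tuple(multipliers), seed=seed
    )
    sign = 1.0 if naive.estimate >= 0 else -1.0

    std_data, scaling = sim.standardize_for_sensitivity(data)
    directions = ("toward-null", "away-from-null")

    for method in methods:
        try:
            if method == "partial_r2":
                bench = pr2.benchmark_partial_r2(data, naive)[0]
                report.strongest[method] = bench.to_dict()
                for k in multipliers:
                    for d in directions:
                        params = pr2.PartialR2Params(
                            min(k * bench.values["r2_xu"], 1 - 1e-6),
                            min(k * bench.values["r2_yu"], 1 - 1e-6),
                            d,
                        )
                        cell = _cell_from_adjusted(pr2.adjust(naive, params, conf_level))
                        report.cells[(method, d, k)] = cell
            elif method == "threshold":
                bench = thr.benchmark_correlations(data)[0]
                report.strongest[method] = bench.to_dict()
                rx, ry = abs(bench.values["r_xu"]), abs(bench.values["r_yu"])
                for k in multipliers:
                    rxk = min(k * rx, 0.995)
                    ryk = min(k * ry, 0.995)
                    for d in directions:
                        # product sign sets the bias direction relative to the estimate
                        s = sign if d == "toward-null" else -sign
                        res = thr.adjust_estimate(
                            naive, thr.CorrelationParams(s * rxk, ryk), conf_level
                        )
                        report.cells[(method, d, k)] = {
                            "estimate": None,
                            "verdict": "excludes 0" if res.significant else "includes 0",
                            "significant": res.significant,
                        }
            elif method == "confounding_function":
                _, benches = cf.sensitivity_curve(data, [0.0], conf_level)
                bench = benches[0]
                report.strongest[method] = bench.to_dict()
                p = cf.propensity(data)
                slope = cf.adjustment_slope(data, p)
                toward = 1.0 if slope * sign > 0 else -1.0
                for k in multipliers:
                    a_mag = float(np.sqrt(k * bench.values["r2_alpha_magnitude"] * naive.sigma2))
                    for d in directions:
                        a = toward * a_mag if d == "toward-null" else -toward * a_mag
                        res = cf._refit(data, cf.adjust_outcome(data, p, a), conf_level)
                        res.params.update({"alpha_raw": a})
                        report.cells[(method, d, k)] = _cell_from_adjusted(res)
            elif method == "simulation":
                bench = sim.benchmark_coefficients(std_data)[0]
                report.strongest[method] = bench.to_dict()
                bzy, bzx = bench.values["zeta_y"], bench.values["zeta_x"]
                base = sim_params or sim.SimulationParams(
                    zeta_y=0.0, zeta_x=0.0, iterations=30, burn_in=10, chains=4, seed=seed
                )
                from dataclasses import replace as _replace

                for k in multipliers:
                    for d in directions:
                        # same-sign (zy, zx) product matching the estimate's sign biases
                        # toward the null; flipping zeta_y reverses the direction
                        zy = sign * abs(k * bzy) if d == "toward-null" else -sign * abs(k * bzy)
                        zx = abs(k * bzx)
                        res = sim.run_simulation_qba(
                            std_data, _replace(base, zeta_y=zy, zeta_x=zx), conf_level
                        )
                        adj = res.to_adjusted()
                        cell = _cell_from_adjusted(adj)
                        for key in ("estimate", "se", "ci_low", "ci_high"):
                            cell[key] = scaling.estimate_to_original(cell[key])
                        report.cells[(method, d, k)] = cell
        except Exception as exc:  # per-cell capture: a method failure must not kill the report
            for k in multipliers:
                for d in directions:
                    report.cells.setdefault((method, d, k), {"error": str(exc)})
    return report
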