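"""Shared result containers: adjusted estimates, benchmarks, contours, tipping points."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AdjustedResult", "BenchmarkEntry", "GridSpec", "ContourSet", "TippingPoint"]


@dataclass(frozen=True)
class AdjustedResult:
    """A bias-adjusted exposure effect with its interval and t value."""

    estimate: float
    se: float
    t_value: float
    df: int
    ci_low: float
    ci_high: float
    conf_level: float
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be nonnegative")
        if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain the estimate")

    @property
    def significant(self) -> bool:
        """Whether the interval excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "t_value": self.t_value,
            "df": self.df,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "conf_level": self.conf_level,
            "method": self.method,
            "params": self.params,
        }


def make_adjusted(
    estimate: float,
    se: float,
    df: int,
    conf_level: float,
    method: str,
    params: dict[str, Any] | None = None,
) -> AdjustedResult:
    """Build an AdjustedResult with a Student-t interval at the given df."""
    tq = stats.t.ppf((1 + conf_level) / 2, df)
    t_value = estimate / se if se > 0 else math.copysign(math.inf, estimate) if estimate else 0.0
    return AdjustedResult(
        estimate=float(estimate),
        se=float(se),
        t_value=float(t_value),
        df=int(df),
        ci_low=float(estimate - tq * se),
        ci_high=float(estimate + tq * se),
        conf_level=conf_level,
        method=method,
        params=dict(params or {}),
    )


@dataclass(frozen=True)
class BenchmarkEntry:
    """A measured covariate's strength expressed on one method's bias-parameter scale.

    Benchmarks are *informal*: they report how strongly measured covariates
    associate with exposure and outcome, as reference points for judging a
    hypothetical confounder, without adjusting for the omission of U itself.
    """

    name: str
    label: str
    scale: str  # method tag: partial_r2 | correlation | evalue | coefficients | r2_alpha
    values: dict[str, float]
    strength: float
    note: str = "informal benchmark"

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "label": self.label,
            "scale": self.scale,
            "values": self.values,
            "strength": self.strength,
            "note": self.note,
        }


@dataclass(frozen=True)
class GridSpec:
    """Rectangular evaluation grid for two bias parameters."""

    x_min: float = 0.0
    x_max: float = 0.4
    y_min: float = 0.0
    y_max: float = 0.4
    resolution: int = 201

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(self.x_min, self.x_max, self.resolution),
            np.linspace(self.y_min, self.y_max, self.resolution),
        )


@dataclass
class ContourSet:
    """A surface of adjusted results over a bias-parameter grid plus level sets.

    ``values[i, j]`` is the surface at ``x[j]`` (first parameter) and ``y[i]``
    (second parameter).  ``levels`` maps a tag (e.g. ``"null"``,
    ``"critical_t"``) to a list of polyline arrays of shape (k, 2) in
    (x, y) coordinates.
    """

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    target: str
    levels: dict[str, list[np.ndarray]] = field(default_factory=dict)
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        rows = pd.DataFrame(
            {
                self.x_name: xx.ravel(),
                self.y_name: yy.ravel(),
                "value": self.values.ravel(),
                "level_tag": "",
            }
        )
        level_rows = [
            pd.DataFrame(
                {
                    self.x_name: seg[:, 0],
                    self.y_name: seg[:, 1],
                    "value": np.nan,
                    "level_tag": tag,
                }
            )
            for tag, segs in self.levels.items()
            for seg in segs
        ]
        return pd.concat([rows, *level_rows], ignore_index=True)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "x_name": self.x_name,
                "y_name": self.y_name,
                "x": self.x.tolist(),
                "y": self.y.tolist(),
                "values": self.values.tolist(),
                "target": self.target,
                "levels": {t: [s.tolist() for s in segs] for t, segs in self.levels.items()},
                "note": self.note,
            }
        )


def extract_levels(
    x: np.ndarray, y: np.ndarray, values: np.ndarray, level: float
) -> list[np.ndarray]:
    """Level-set polylines of a gridded surface, in data coordinates.

    Uses marching squares on the gridded surface; contour vertices are linear
    interpolations between grid nodes.
    """
    from skimage import measure

    if not (np.nanmin(values) <= level <= np.nanmax(values)):
        return []
    segs = measure.find_contours(values, level)
    out = []
    for seg in segs:
        # find_contours returns (row, col) = (y index, x index)
        xs = np.interp(seg[:, 1], np.arange(len(x)), x)
        ys = np.interp(seg[:, 0], np.arange(len(y)), y)
        out.append(np.column_stack([xs, ys]))
    return out


@dataclass(frozen=True)
class TippingPoint:
    """A solved locus where a study conclusion changes, with self-verification.

    ``value`` is the scalar position along the method's one-dimensional path
    (the equal-parameter diagonal for two-parameter methods).  ``residual`` is
    the criterion value re-evaluated at the locus; ``verified`` confirms it is
    within ``tolerance``.
    """

    method: str
    criterion: str  # "null-estimate" | "significance"
    value: float
    residual: float
    tolerance: float
    verified: bool
    benchmark_multiple: float | None = None
    alpha: float | None = None
    note: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "criterion": self.criterion,
            "value": self.value,
            "residual": self.residual,
            "tolerance": self.tolerance,
            "verified": self.verified,
            "benchmark_multiple": self.benchmark_multiple,
            "alpha": self.alpha,
            "note": self.note,
        }
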