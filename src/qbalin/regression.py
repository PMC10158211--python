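"""Naive-model fitting and recovery of regression summaries from published numbers.

Every bias-analysis method in this package conditions on the same observed-data
regression: an ordinary least squares fit of a continuous outcome ``Y`` on a
binary exposure ``X`` and measured covariates ``C``.  The coefficient of ``X``
from that fit is the *naive* exposure effect -- "naive" because it adjusts for
the measured covariates only, leaving any unmeasured confounder ``U``
unaccounted for.

Two entry points produce the :class:`NaiveFit` that the method modules consume:

* :func:`fit_naive` -- fit the model to unit-record data;
* :func:`summary_from_published` -- reconstruct the fit summary (SE, t, df)
  from a published point estimate, confidence interval, sample size and
  covariate count, for methods that need only summary statistics.

A probit fit of the exposure on covariates (:func:`fit_probit`) supports the
latent-confounder simulation method, which uses a probit treatment model for a
binary exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "Dataset",
    "NaiveFit",
    "ProbitFit",
    "fit_naive",
    "summary_from_published",
    "fit_probit",
    "partial_stats",
]


@dataclass(frozen=True)
class Dataset:
    """Complete-case unit-record data for one exposure-outcome analysis.

    Parameters
    ----------
    y : array of float
        Continuous outcome, in analysis units (e.g. kg/m^2 for BMI).
    x : array of float
        Binary exposure coded 0/1.
    covariates : 2-d array, shape (n, p)
        Measured covariates; binary covariates coded 0/1.  May have zero
        columns.
    covariate_names : sequence of str
        One name per covariate column.
    """

    y: np.ndarray
    x: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()
    outcome_name: str = "y"
    exposure_name: str = "x"

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=float)
        C = np.asarray(self.covariates, dtype=float)
        if C.ndim == 1:
            C = C.reshape(-1, 1) if C.size else C.reshape(len(y), 0)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "covariates", C)
        if not self.covariate_names and C.shape[1]:
            object.__setattr__(
                self, "covariate_names", tuple(f"c{j + 1}" for j in range(C.shape[1]))
            )
        else:
            object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        self._validate()

    def _validate(self) -> None:
        n = len(self.y)
        if len(self.x) != n or self.covariates.shape[0] != n:
            raise ValueError("outcome, exposure and covariates must have equal length")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length must match covariate columns")
        for name, arr in ((self.outcome_name, self.y), (self.exposure_name, self.x)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(f"missing/non-finite values in '{name}' at rows {bad[:5].tolist()}")
        bad_rows = np.flatnonzero(~np.isfinite(self.covariates).all(axis=1))
        if bad_rows.size:
            raise ValueError(f"missing/non-finite covariate values at rows {bad_rows[:5].tolist()}")
        levels = np.unique(self.x)
        if not np.isin(levels, (0.0, 1.0)).all() or levels.size != 2:
            raise ValueError(f"exposure must take exactly the two values 0 and 1; saw {levels[:5]}")
        if n <= self.n_params + 2:
            raise ValueError(f"n = {n} too small for {self.n_params} model parameters")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_params(self) -> int:
        """Parameters of the naive model: intercept + exposure + covariates."""
        return 2 + self.n_covariates

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        exposure: str,
        covariates: Sequence[str] | None = None,
    ) -> "Dataset":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (outcome, exposure)]
        missing = [c for c in [outcome, exposure, *covariates] if c not in df.columns]
        if missing:
            raise ValueError(f"columns not found: {missing}")
        sub = df[[outcome, exposure, *covariates]]
        na = sub.isna()
        if na.any().any():
            rows = na.any(axis=1)
            raise ValueError(f"missing cells at rows {sub.index[rows][:5].tolist()}")
        return cls(
            y=sub[outcome].to_numpy(dtype=float),
            x=sub[exposure].to_numpy(dtype=float),
            covariates=sub[list(covariates)].to_numpy(dtype=float),
            covariate_names=tuple(covariates),
            outcome_name=outcome,
            exposure_name=exposure,
        )

    @classmethod
    def from_csv(
        cls,
        path: str,
        outcome: str,
        exposure: str,
        covariates: Sequence[str] | None = None,
    ) -> "Dataset":
        """Read a comma-separated file with a header row ('.' decimal point)."""
        return cls.from_dataframe(pd.read_csv(path), outcome, exposure, covariates)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({self.outcome_name: self.y, self.exposure_name: self.x})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    def drop_covariate(self, name: str) -> "Dataset":
        if name not in self.covariate_names:
            raise KeyError(name)
        keep = [j for j, c in enumerate(self.covariate_names) if c != name]
        return replace(
            self,
            covariates=self.covariates[:, keep],
            covariate_names=tuple(self.covariate_names[j] for j in keep),
        )

    def with_covariate(self, name: str, values: np.ndarray) -> "Dataset":
        """Return a copy with one extra covariate column (e.g. a realized U)."""
        values = np.asarray(values, dtype=float).reshape(-1)
        return replace(
            self,
            covariates=np.column_stack([self.covariates, values]),
            covariate_names=(*self.covariate_names, name),
        )


@dataclass(frozen=True)
class NaiveFit:
    """Summary of the observed-data regression of Y on (1, X, C).

    ``estimate`` is the naive exposure effect in outcome units.  When built
    from unit-record data, ``covariates`` holds per-covariate association
    summaries used for benchmarking; when built from published numbers it is
    ``None`` (benchmarking then requires the data).
    """

    estimate: float
    se: float
    t_value: float
    df: int
    n: int
    n_params: int
    conf_level: float = 0.95
    sigma2: float | None = None
    degenerate: bool = False
    covariates: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def partial_r2_exposure(self) -> float:
        """Partial R^2 of the exposure with the outcome given covariates."""
        t2 = self.t_value**2
        return t2 / (t2 + self.df)

    @property
    def partial_corr_exposure(self) -> float:
        return self.t_value / math.sqrt(self.t_value**2 + self.df)

    def ci(self, conf_level: float | None = None) -> tuple[float, float]:
        """Student-t confidence interval for the naive estimate."""
        level = self.conf_level if conf_level is None else conf_level
        tq = stats.t.ppf((1 + level) / 2, self.df)
        return (self.estimate - tq * self.se, self.estimate + tq * self.se)

    def critical_t(self, alpha: float, df: int | None = None) -> float:
        return float(stats.t.ppf(1 - alpha / 2, self.df if df is None else df))

    @property
    def has_data_summaries(self) -> bool:
        return self.covariates is not None


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood probit fit of a binary exposure on covariates."""

    coefficients: np.ndarray  # intercept first
    names: tuple[str, ...]
    loglike: float
    fitted_probs: np.ndarray
    converged: bool
    offset_used: bool = False


def _design(data: Dataset) -> np.ndarray:
    return np.column_stack([np.ones(data.n), data.x, data.covariates])


def _check_rank(M: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank == M.shape[1]:
        return
    # identify columns whose removal does not reduce the rank (collinear set)
    collinear = [
        names[j]
        for j in range(M.shape[1])
        if np.linalg.matrix_rank(np.delete(M, j, axis=1)) == rank
    ]
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def partial_stats(response: np.ndarray, regressors: np.ndarray) -> pd.DataFrame:
    """Per-regressor t statistics, partial R^2 and partial correlations.

    Fits OLS of ``response`` on an intercept plus ``regressors`` and converts
    each slope's t statistic into the partial R^2 (t^2/(t^2+df)) and partial
    correlation (t/sqrt(t^2+df)) of that regressor with the response given the
    remaining regressors.
    """
    M = np.column_stack([np.ones(len(response)), regressors])
    res = sm.OLS(response, M).fit()
    df = int(res.df_resid)
    t = np.asarray(res.tvalues)[1:]
    return pd.DataFrame(
        {
            "coef": np.asarray(res.params)[1:],
            "t": t,
            "partial_r2": t**2 / (t**2 + df),
            "partial_corr": t / np.sqrt(t**2 + df),
        }
    )


def fit_naive(data: Dataset, alpha: float = 0.05) -> NaiveFit:
    """OLS of Y on (1, X, C) with benchmarking summaries for each covariate.

    For every regressor z the partial R^2 is computed as t_z^2/(t_z^2 + df)
    and the partial correlation as t_z/sqrt(t_z^2 + df).  Covariate
    associations with the exposure come from an auxiliary regression of X on
    the remaining covariates.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    M = _design(data)
    names = ["(intercept)", data.exposure_name, *data.covariate_names]
    _check_rank(M, names)
    res = sm.OLS(data.y, M).fit()
    df = int(res.df_resid)
    sigma2 = float(res.ssr / df)
    scale_tol = max(float(np.var(data.y)), 1.0) * 1e-12
    degenerate = sigma2 <= scale_tol

    cov_summary: pd.DataFrame | None = None
    if data.n_covariates:
        t_y = np.asarray(res.tvalues)[2:]
        with np.errstate(invalid="ignore"):
            y_part = pd.DataFrame(
                {
                    "coef": np.asarray(res.params)[2:],
                    "partial_r2_y": t_y**2 / (t_y**2 + df),
                    "partial_corr_y": t_y / np.sqrt(t_y**2 + df),
                },
                index=list(data.covariate_names),
            )
        x_part = partial_stats(data.x, data.covariates)
        cov_summary = y_part.assign(
            partial_r2_x=x_part["partial_r2"].to_numpy(),
            partial_corr_x=x_part["partial_corr"].to_numpy(),
        )
    else:
        cov_summary = pd.DataFrame(
            columns=["coef", "partial_r2_y", "partial_corr_y", "partial_r2_x", "partial_corr_x"]
        )

    estimate = float(res.params[1])
    se = float(res.bse[1]) if not degenerate else 0.0
    t_value = estimate / se if se > 0 else float("nan")
    return NaiveFit(
        estimate=estimate,
        se=se,
        t_value=t_value,
        df=df,
        n=data.n,
        n_params=data.n_params,
        conf_level=1 - alpha,
        sigma2=sigma2,
        degenerate=degenerate,
        covariates=cov_summary,
    )


def summary_from_published(
    estimate: float,
    ci_low: float,
    ci_high: float,
    conf_level: float = 0.95,
    n: int = 0,
    n_covariates: int = 0,
) -> NaiveFit:
    """Recover (se, t, df) from a published estimate and confidence interval.

    Degrees of freedom follow the naive-model convention df = n - covariates
    - 2 (intercept and exposure).  The SE is recovered from the CI width using
    the Student t quantile at that df, e.g. the published summary
    ``(2.21, [1.30, 3.11], n=542, 7 covariates)`` gives se ~= 0.461 and
    t ~= 4.80 on 533 degrees of freedom.
    """
    if not (ci_low < estimate < ci_high):
        raise ValueError("confidence interval must satisfy ci_low < estimate < ci_high")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    n_params = n_covariates + 2
    df = n - n_params
    if df <= 2:
        raise ValueError(f"n = {n} too small for {n_covariates} covariates")
    tq = stats.t.ppf((1 + conf_level) / 2, df)
    se = (ci_high - ci_low) / (2 * tq)
    return NaiveFit(
        estimate=float(estimate),
        se=float(se),
        t_value=float(estimate / se),
        df=int(df),
        n=int(n),
        n_params=n_params,
        conf_level=conf_level,
        sigma2=None,
        covariates=None,
    )


def fit_probit(
    x: np.ndarray,
    covariates: np.ndarray,
    offset: np.ndarray | None = None,
    names: Sequence[str] | None = None,
) -> ProbitFit:
    """Deterministic maximum-likelihood probit of a binary x on covariates.

    Newton iterations start from the zero vector, so repeated fits on the same
    data are bit-identical.  ``offset`` is a fixed per-row addend on the linear
    predictor (used by the simulation method to hold the latent confounder's
    coefficient fixed).
    """
    x = np.asarray(x, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C.reshape(-1, 1) if C.size else C.reshape(len(x), 0)
    levels = np.unique(x)
    if not np.isin(levels, (0.0, 1.0)).all():
        raise ValueError("x must be binary 0/1")
    M = np.column_stack([np.ones(len(x)), C])
    col_names = tuple(names) if names else ("(intercept)", *(f"c{j+1}" for j in range(C.shape[1])))
    _check_rank(M, col_names)
    import warnings

    model = sm.Probit(x, M, offset=offset)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(
                method="newton", start_params=np.zeros(M.shape[1]), disp=0, warn_convergence=False
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(f"perfect separation in probit fit: {exc}") from exc
    probs = np.asarray(res.predict())
    eps = 1e-12
    if np.any(probs <= eps) or np.any(probs >= 1 - eps):
        raise ValueError("probit fit produced degenerate fitted probabilities (separation?)")
    return ProbitFit(
        coefficients=np.asarray(res.params),
        names=col_names,
        loglike=float(res.llf),
        fitted_probs=probs,
        converged=bool(res.mle_retvals.get("converged", True)),
        offset_used=offset is not None,
    )
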