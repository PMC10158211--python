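"""Latent-confounder simulation: draw U compatible with the data, refit, summarise.

The unmeasured confounder enters two working models with *fixed* sensitivity
coefficients (the bias parameters):

* outcome:   Y = tau*X + C*gamma + zeta_y * U + eps,   eps ~ N(0, sigma^2)
* treatment: X ~ Bernoulli( Phi(C*delta + zeta_x * U) )   (probit link)

For prespecified (zeta_y, zeta_x) a stochastic-EM loop alternates between
(1) fitting the outcome model by OLS of Y - zeta_y*U on (1, X, C) and the
treatment model by probit of X on C with offset zeta_x*U, and (2) redrawing
each U_i from its exact conditional distribution given (Y_i, X_i, C_i) under
the current fits.  The exposure-coefficient draws after burn-in are combined
as multiple imputations of U: the reported variance is the mean within-draw
variance plus (1 + 1/m) times the between-draw variance.

Because zeta_y and zeta_x are held fixed (offsets, not free coefficients),
setting zeta_y = 0 makes every kept draw equal the naive estimate exactly --
a conservation law the tests verify draw by draw.

U may be binary with marginal probability ``p_u`` (default 0.5) or standard
normal; the normal case uses truncated-normal augmentation of the probit so
the conditional draw of U stays exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .regression import Dataset, fit_naive, fit_probit
from .results import AdjustedResult, BenchmarkEntry, ContourSet, extract_levels, make_adjusted

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "ScalingRecord",
    "standardize_for_sensitivity",
    "draw_u_conditional",
    "run_simulation_qba",
    "benchmark_coefficients",
    "tipping_grid",
]


@dataclass(frozen=True)
class SimulationParams:
    """Sensitivity coefficients and sampler settings.

    ``zeta_y`` is U's coefficient in the outcome model (outcome units of the
    data as supplied; SD-of-Y units if the data were standardized first);
    ``zeta_x`` is U's probit coefficient in the treatment model.  ``iterations``
    counts sampler sweeps per chain, the first ``burn_in`` of which are
    discarded; ``chains`` independent chains are pooled.
    """

    zeta_y: float
    zeta_x: float
    p_u: float = 0.5
    u_type: str = "binary"  # or "standard-normal"
    iterations: int = 60
    burn_in: int = 10
    chains: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_u < 1:
            raise ValueError("p_u must be in (0, 1)")
        if self.u_type not in ("binary", "standard-normal"):
            raise ValueError("u_type must be 'binary' or 'standard-normal'")
        if not self.iterations > self.burn_in >= 1:
            raise ValueError("need iterations > burn_in >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass(frozen=True)
class SimulationResult:
    """Pooled bias-adjusted estimate over the kept draws of U."""

    estimate: float
    within_var: float
    between_var: float
    total_se: float
    df: int
    conf_level: float
    trace: np.ndarray = field(repr=False)  # (chains, kept) exposure-coefficient draws
    se_trace: np.ndarray = field(repr=False)
    split_half_diff: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.trace.size

    def to_adjusted(self, method: str = "simulation") -> AdjustedResult:
        return make_adjusted(
            self.estimate, self.total_se, self.df, self.conf_level, method, self.params
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "within_var": self.within_var,
            "between_var": self.between_var,
            "total_se": self.total_se,
            "df": self.df,
            "conf_level": self.conf_level,
            "split_half_diff": self.split_half_diff,
            "seed": self.seed,
            "params": self.params,
            "trace": self.trace.tolist(),
        }


@dataclass(frozen=True)
class ScalingRecord:
    """Centering/scaling applied before a sensitivity analysis; supports back-transform."""

    y_mean: float
    y_sd: float
    cov_means: np.ndarray
    cov_sds: np.ndarray
    binary_mask: np.ndarray

    def estimate_to_original(self, value: float) -> float:
        """Map an exposure-effect estimate (or SE) from SD-of-Y units back to outcome units."""
        return value * self.y_sd


def _is_binary(col: np.ndarray) -> bool:
    return bool(np.isin(np.unique(col), (0.0, 1.0)).all())


def standardize_for_sensitivity(data: Dataset) -> tuple[Dataset, ScalingRecord]:
    """Center/scale the outcome and continuous covariates to unit SD.

    Binary 0/1 columns (and the exposure) are left untouched so that probit
    coefficients keep their natural interpretation.  Idempotent: applying it
    to already-standardized data is a no-op.
    """
    y_sd = float(np.std(data.y, ddof=1))
    if y_sd == 0:
        raise ValueError("outcome has zero variance")
    y_mean = float(np.mean(data.y))
    C = data.covariates.copy()
    p = C.shape[1]
    means = np.zeros(p)
    sds = np.ones(p)
    mask = np.zeros(p, dtype=bool)
    for j in range(p):
        if _is_binary(C[:, j]):
            mask[j] = True
            continue
        sd = float(np.std(C[:, j], ddof=1))
        if sd == 0:
            raise ValueError(f"covariate '{data.covariate_names[j]}' has zero variance")
        means[j] = float(np.mean(C[:, j]))
        sds[j] = sd
        C[:, j] = (C[:, j] - means[j]) / sd
    std = replace(data, y=(data.y - y_mean) / y_sd, covariates=C)
    return std, ScalingRecord(y_mean, y_sd, means, sds, mask)


def draw_u_conditional(
    y: np.ndarray,
    x: np.ndarray,
    mu: np.ndarray,
    sigma2: float,
    eta: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One exact draw of binary U_i | (Y_i, X_i, C_i) under the current fits.

    ``mu`` is the outcome linear predictor without the U term and ``eta`` the
    treatment probit linear predictor without the U term.  Per row the two
    candidate values u in {0, 1} are weighted by
    prior * N(y; mu + zeta_y u, sigma2) * Phi(eta + zeta_x u)^x *
    (1 - Phi(eta + zeta_x u))^(1-x), and U_i is Bernoulli with the
    normalised weight of u = 1.
    """
    zy, zx, pu = params.zeta_y, params.zeta_x, params.p_u
    lw = []
    for u in (0.0, 1.0):
        prior = math.log(pu) if u else math.log(1 - pu)
        ll_y = -0.5 * (y - mu - zy * u) ** 2 / sigma2
        e = eta + zx * u
        ll_x = np.where(x == 1, stats.norm.logcdf(e), stats.norm.logcdf(-e))
        lw.append(prior + ll_y + ll_x)
    bad = np.flatnonzero(~(np.isfinite(lw[0]) | np.isfinite(lw[1])))
    if bad.size:
        raise ValueError(f"non-finite conditional weights for U at rows {bad[:5].tolist()}")
    with np.errstate(over="ignore"):
        p1 = 1.0 / (1.0 + np.exp(lw[0] - lw[1]))
    return (rng.random(len(y)) < p1).astype(float)


def _draw_u_normal(
    y: np.ndarray,
    x: np.ndarray,
    mu: np.ndarray,
    sigma2: float,
    eta: np.ndarray,
    u: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gibbs update of standard-normal U via truncated-normal probit augmentation."""
    zy, zx = params.zeta_y, params.zeta_x
    # latent z | x, u ~ N(eta + zx*u, 1) truncated to the half-line matching x
    m = eta + zx * u
    lo = np.where(x == 1, -m, -np.inf)
    hi = np.where(x == 1, np.inf, -m)
    z = m + stats.truncnorm.rvs(lo, hi, size=len(y), random_state=rng)
    # U | y, z ~ normal: prior N(0,1), likelihoods N(y; mu+zy*U, s2), N(z; eta+zx*U, 1)
    prec = 1.0 + zy**2 / sigma2 + zx**2
    mean = (zy * (y - mu) / sigma2 + zx * (z - eta)) / prec
    return mean + rng.standard_normal(len(y)) / math.sqrt(prec)


def _probit_fisher(
    x: np.ndarray, M: np.ndarray, offset: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Fast Fisher-scoring probit with fixed offset, started at zero.

    Matches :func:`qbalin.regression.fit_probit` on the same data; used in the
    sampler's inner loop where per-iteration overhead matters.
    """
    b = np.zeros(M.shape[1])
    for it in range(max_iter):
        eta = M @ b + offset
        p = stats.norm.cdf(eta)
        phi = stats.norm.pdf(eta)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        w = phi**2 / (p * (1 - p))
        score = M.T @ (phi * (x - p) / (p * (1 - p)))
        info = (M * w[:, None]).T @ M
        ridge = 1e-10 * max(np.trace(info) / M.shape[1], 1e-10)
        try:
            step = np.linalg.solve(info + ridge * np.eye(M.shape[1]), score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"probit information matrix singular (separation?): {exc}") from exc
        # damp early overshoots at extreme offsets
        biggest = np.max(np.abs(step))
        if biggest > 4.0:
            step *= 4.0 / biggest
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ValueError("probit fit did not converge (separation?)")
    if np.max(np.abs(M @ b + offset)) > 30:
        raise ValueError("probit linear predictor diverged (perfect separation?)")
    return b


def run_simulation_qba(
    data: Dataset, params: SimulationParams, conf_level: float = 0.95
) -> SimulationResult:
    """Stochastic-EM bias adjustment at fixed (zeta_y, zeta_x).

    Runs ``params.chains`` independent chains of ``params.iterations`` sweeps
    each, keeps the exposure-coefficient draws after ``params.burn_in``, and
    pools them with the multiple-imputation variance rule
    total = within + (1 + 1/m) * between.  Deterministic given the seed.
    """
    n = data.n
    M = np.column_stack([np.ones(n), data.x, data.covariates])
    k = M.shape[1]
    Q, R = np.linalg.qr(M)
    xtx_inv_diag = float(np.linalg.inv(R.T @ R)[1, 1])
    M2 = np.column_stack([np.ones(n), data.covariates])
    df = n - k
    kept = params.iterations - params.burn_in
    trace = np.empty((params.chains, kept))
    se_trace = np.empty((params.chains, kept))
    seeds = np.random.SeedSequence(params.seed).spawn(params.chains)

    for c in range(params.chains):
        rng = np.random.default_rng(seeds[c])
        if params.u_type == "binary":
            u = (rng.random(n) < params.p_u).astype(float)
        else:
            u = rng.standard_normal(n)
        for it in range(params.iterations):
            resp = data.y - params.zeta_y * u
            beta = np.linalg.solve(R, Q.T @ resp)
            resid = resp - M @ beta
            sigma2 = float(resid @ resid) / df
            if sigma2 <= 0:
                raise ValueError(f"degenerate residual variance at iteration {it}")
            try:
                delta = _probit_fisher(data.x, M2, params.zeta_x * u)
            except ValueError as exc:
                raise ValueError(f"treatment-model failure at iteration {it}: {exc}") from exc
            mu = M @ beta
            eta = M2 @ delta
            if params.u_type == "binary":
                u = draw_u_conditional(data.y, data.x, mu, sigma2, eta, params, rng)
            else:
                u = _draw_u_normal(data.y, data.x, mu, sigma2, eta, u, params, rng)
            if it >= params.burn_in:
                j = it - params.burn_in
                trace[c, j] = beta[1]
                se_trace[c, j] = math.sqrt(sigma2 * xtx_inv_diag)

    flat = trace.ravel()
    m = flat.size
    estimate = float(flat.mean())
    within = float(np.mean(se_trace.ravel() ** 2))
    between = float(np.var(flat, ddof=1)) if m > 1 else 0.0
    total_se = math.sqrt(within + (1 + 1 / m) * between)
    half = m // 2
    split = float(abs(flat[:half].mean() - flat[half:].mean())) if half else 0.0
    return SimulationResult(
        estimate=estimate,
        within_var=within,
        between_var=between,
        total_se=total_se,
        df=df,
        conf_level=conf_level,
        trace=trace,
        se_trace=se_trace,
        split_half_diff=split,
        seed=params.seed,
        params={
            "zeta_y": params.zeta_y,
            "zeta_x": params.zeta_x,
            "p_u": params.p_u,
            "u_type": params.u_type,
            "iterations": params.iterations,
            "burn_in": params.burn_in,
            "chains": params.chains,
        },
    )


def benchmark_coefficients(data: Dataset) -> list[BenchmarkEntry]:
    """Covariate coefficients on the (zeta_y, zeta_x) scale, for standardized data.

    For each covariate: its coefficient in the OLS outcome model Y|X,C and its
    probit coefficient in the treatment model X|C.  Covariates negatively
    associated with the outcome additionally get a sign-rectified copy (both
    coefficients multiplied by -1) so that all benchmarks live in the
    zeta_y >= 0 half-plane alongside positive-association covariates.
    """
    ols = fit_naive(data)
    probit = fit_probit(data.x, data.covariates, names=("(intercept)", *data.covariate_names))
    entries: list[BenchmarkEntry] = []
    for j, name in enumerate(data.covariate_names):
        zy = float(ols.covariates.loc[name, "coef"])
        zx = float(probit.coefficients[1 + j])
        entries.append(
            BenchmarkEntry(
                name=name,
                label=f"1x {name}",
                scale="coefficients",
                values={"zeta_y": zy, "zeta_x": zx},
                strength=abs(zy * zx),
            )
        )
        if zy < 0:
            entries.append(
                BenchmarkEntry(
                    name=name,
                    label=f"1x {name} (rescaled by -1)",
                    scale="coefficients",
                    values={"zeta_y": -zy, "zeta_x": -zx},
                    strength=abs(zy * zx),
                    note="informal benchmark; negative outcome association rescaled by -1",
                )
            )
    entries.sort(key=lambda e: e.strength, reverse=True)
    return entries


def tipping_grid(
    data: Dataset,
    zeta_x_values: Sequence[float],
    zeta_y_values: Sequence[float],
    params: SimulationParams,
    conf_level: float = 0.95,
) -> ContourSet:
    """Adjusted-estimate surface over a (zeta_x, zeta_y) grid with tipping contours.

    Each node reruns the sampler with a seed derived deterministically from
    ``params.seed`` and the node index.  Extracted contours: the null estimate
    and the locus where the confidence interval touches zero (loss of
    significance).  The zeta_y = 0 row equals the naive estimate by the
    conservation law.
    """
    xs = np.asarray(list(zeta_x_values), dtype=float)
    ys = np.asarray(list(zeta_y_values), dtype=float)
    est = np.empty((len(ys), len(xs)))
    margin = np.empty_like(est)  # estimate - t_crit * se (signed toward zero for naive > 0)
    naive = fit_naive(data, alpha=1 - conf_level)
    sign = 1.0 if naive.estimate >= 0 else -1.0
    for i, zy in enumerate(ys):
        for j, zx in enumerate(xs):
            seed = int(np.random.SeedSequence([params.seed, i, j]).generate_state(1)[0] % (2**31))
            p = replace(params, zeta_y=float(zy), zeta_x=float(zx), seed=seed)
            res = run_simulation_qba(data, p, conf_level)
            tq = stats.t.ppf((1 + conf_level) / 2, res.df)
            est[i, j] = res.estimate
            margin[i, j] = sign * res.estimate - tq * res.total_se
    cs = ContourSet(
        x_name="zeta_x",
        y_name="zeta_y",
        x=xs,
        y=ys,
        values=est,
        target="estimate",
        note=f"chains={params.chains}, iterations={params.iterations}, seed={params.seed}",
    )
    cs.levels["null"] = extract_levels(xs, ys, est, 0.0)
    cs.levels["significance"] = extract_levels(xs, ys, margin, 0.0)
    return cs
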