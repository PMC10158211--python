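"""Run configuration: YAML schema, validation, and the orchestrated run.

A run takes either unit-record data (CSV path plus column roles) or a
summary-statistics block (point estimate, CI, n, covariate count), a list of
methods, and analysis settings.  Validation collects *all* schema violations
before reporting; methods that need unit-record data are rejected up front in
summary-only mode with a clear message.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

logger = logging.getLogger(__name__)

VALID_METHODS = ("partial_r2", "evalue", "threshold", "confounding_function", "simulation")
DATA_ONLY_METHODS = ("confounding_function", "simulation")

__all__ = ["RunConfig", "load_config", "validate_config", "run", "VALID_METHODS"]


@dataclass
class RunConfig:
    methods: list[str]
    output_dir: str
    data_path: str | None = None
    outcome: str | None = None
    exposure: str | None = None
    covariates: list[str] | None = None
    summary: dict[str, float] | None = None
    alpha: float = 0.05
    q: float = 1.0
    sd_outcome: float | None = None
    multipliers: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0])
    grid: dict[str, float] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)
    benchmarks: bool = True
    report: bool = False
    seed: int = 0

    @property
    def summary_only(self) -> bool:
        return self.data_path is None

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SUMMARY_KEYS = ("estimate", "ci_low", "ci_high", "n", "n_covariates")


def validate_config(raw: dict[str, Any]) -> tuple[RunConfig | None, list[str]]:
    """Validate a raw config mapping; returns (config, errors) with all errors listed."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    methods = raw.get("methods") or []
    if not methods:
        errors.append("methods: at least one method required")
    bad = [m for m in methods if m not in VALID_METHODS]
    if bad:
        errors.append(f"methods: unknown {bad}; valid names are {list(VALID_METHODS)}")
    data = raw.get("data") or {}
    summary = raw.get("summary")
    if bool(data) == bool(summary is not None):
        errors.append("exactly one of 'data' and 'summary' must be given")
    if data:
        for key in ("path", "outcome", "exposure"):
            if not data.get(key):
                errors.append(f"data.{key} is required")
    if summary is not None:
        for key in _SUMMARY_KEYS:
            if key not in summary:
                errors.append(f"summary.{key} is required")
        data_only = [m for m in methods if m in DATA_ONLY_METHODS]
        if data_only:
            errors.append(
                f"methods {data_only} require unit-record data and cannot run in summary mode"
            )
        if raw.get("report"):
            errors.append("comparative report requires data; benchmarking requires data")
    alpha = raw.get("alpha", 0.05)
    if not 0 < alpha < 1:
        errors.append("alpha must be in (0, 1)")
    if not raw.get("output_dir"):
        errors.append("output_dir is required")
    if errors:
        return None, errors
    return (
        RunConfig(
            methods=list(methods),
            output_dir=str(raw["output_dir"]),
            data_path=data.get("path"),
            outcome=data.get("outcome"),
            exposure=data.get("exposure"),
            covariates=data.get("covariates"),
            summary=dict(summary) if summary is not None else None,
            alpha=float(alpha),
            q=float(raw.get("q", 1.0)),
            sd_outcome=raw.get("sd_outcome"),
            multipliers=[float(k) for k in raw.get("multipliers", [0.5, 1.0, 2.0])],
            grid=dict(raw.get("grid", {})),
            simulation=dict(raw.get("simulation", {})),
            benchmarks=bool(raw.get("benchmarks", True)),
            report=bool(raw.get("report", False)),
            seed=int(raw.get("seed", 0)),
        ),
        [],
    )


def load_config(path: str) -> tuple[RunConfig | None, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run(config: RunConfig) -> int:
    """Execute the configured analyses; write artifacts; return an exit status."""
    from . import evalues as ev
    from . import confounding_function as cfun
    from . import partial_r2 as pr2
    from . import simulation as sims
    from . import threshold as thr
    from . import tipping as tip
    from .regression import Dataset, fit_naive, summary_from_published
    from .results import GridSpec

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    log_lines = [f"config_hash: {cfg_hash}", f"seed: {config.seed}"]
    errors: list[dict[str, str]] = []

    data = None
    if config.summary_only:
        s = config.summary
        fit = summary_from_published(
            s["estimate"], s["ci_low"], s["ci_high"],
            s.get("conf_level", 0.95), int(s["n"]), int(s["n_covariates"]),
        )
    else:
        data = Dataset.from_csv(config.data_path, config.outcome, config.exposure, config.covariates)
        fit = fit_naive(data, alpha=config.alpha)
    conf_level = 1 - config.alpha

    for method in config.methods:
        artifact: dict[str, Any] = {"method": method, "config_hash": cfg_hash}
        try:
            if method == "partial_r2":
                artifact["robustness_value_point"] = pr2.robustness_value(fit, q=config.q)
                artifact["robustness_value_t"] = pr2.robustness_value(
                    fit, q=config.q, alpha=config.alpha
                )
                artifact["extreme_confounder_bound"] = pr2.extreme_confounder_bound(fit, q=config.q)
                gs = GridSpec(**config.grid) if config.grid else GridSpec()
                cs = pr2.contour_grid(fit, "estimate", gs, config.alpha)
                cs.to_csv(str(out / "partial_r2_contours.csv"))
                artifact["contour_csv"] = "partial_r2_contours.csv"
                if data is not None and config.benchmarks:
                    artifact["benchmarks"] = [
                        b.to_dict() for b in pr2.benchmark_partial_r2(data, fit)
                    ]
                elif config.benchmarks:
                    artifact["benchmarks"] = "benchmarking requires data"
            elif method == "evalue":
                if data is not None:
                    sd = float(np.std(data.y, ddof=1))
                elif config.sd_outcome:
                    sd = float(config.sd_outcome)
                else:
                    raise ValueError("evalue needs sd_outcome in summary mode")
                eff = ev.rr_from_linear(fit, sd_outcome=sd, conf_level=conf_level)
                e_point, e_ci = ev.evalue_report(eff)
                artifact.update(
                    e_point=e_point, e_ci=e_ci,
                    rr_scale_effect={
                        "rr_point": eff.rr_point, "rr_ci_low": eff.rr_ci_low,
                        "rr_ci_high": eff.rr_ci_high,
                    },
                    conversion={"d": eff.d, "se_d": eff.se_d, "constant": ev.D_TO_RR},
                )
                contour = ev.bias_factor_contour(eff)
                pd_frame = {
                    "rr_xu": contour["rr_xu"].tolist(), "rr_uy": contour["rr_uy"].tolist(),
                }
                _json_dump({**pd_frame, "evalue": contour["evalue"]}, out / "evalue_contour.json")
                artifact["contour_json"] = "evalue_contour.json"
                if data is not None and config.benchmarks:
                    artifact["benchmarks"] = [b.to_dict() for b in ev.benchmark_evalues(data)]
                elif config.benchmarks:
                    artifact["benchmarks"] = "benchmarking requires data"
            elif method == "threshold":
                pb, mode = thr.percent_bias(fit, config.alpha)
                itcv, eq = thr.impact_threshold(fit, config.alpha)
                artifact.update(
                    percent_bias=pb, mode=mode, itcv=itcv, equal_correlation=eq,
                    narrative=thr.narrative_report(fit, config.alpha),
                )
                if data is not None and config.benchmarks:
                    artifact["benchmarks"] = [b.to_dict() for b in thr.benchmark_correlations(data)]
                elif config.benchmarks:
                    artifact["benchmarks"] = "benchmarking requires data"
            elif method == "confounding_function":
                grid = np.round(np.linspace(-0.05, 0.05, 21), 6)
                curve, benches = cfun.sensitivity_curve(data, grid, conf_level)
                rows = [
                    {
                        "r2_alpha": r.params["r2_alpha"], "alpha_raw": r.params["alpha_raw"],
                        "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    }
                    for r in curve
                ]
                import pandas as pd

                pd.DataFrame(rows).to_csv(out / "confounding_function_curve.csv", index=False)
                artifact["curve_csv"] = "confounding_function_curve.csv"
                artifact["benchmarks"] = [b.to_dict() for b in benches]
                path, alpha0 = tip.confounding_function_path(data, alpha=config.alpha)
                artifact["tipping_alpha0"] = alpha0
            elif method == "simulation":
                std, scaling = sims.standardize_for_sensitivity(data)
                sp = sims.SimulationParams(
                    zeta_y=float(config.simulation.get("zeta_y", 0.2)),
                    zeta_x=float(config.simulation.get("zeta_x", 0.2)),
                    p_u=float(config.simulation.get("p_u", 0.5)),
                    u_type=str(config.simulation.get("u_type", "binary")),
                    iterations=int(config.simulation.get("iterations", 60)),
                    burn_in=int(config.simulation.get("burn_in", 10)),
                    chains=int(config.simulation.get("chains", 20)),
                    seed=config.seed,
                )
                res = sims.run_simulation_qba(std, sp, conf_level)
                d = res.to_dict()
                d["estimate_original_units"] = scaling.estimate_to_original(res.estimate)
                d["total_se_original_units"] = scaling.estimate_to_original(res.total_se)
                artifact["result"] = d
                artifact["benchmarks"] = [b.to_dict() for b in sims.benchmark_coefficients(std)]
        except Exception as exc:
            errors.append({"method": method, "error": str(exc)})
            artifact["error"] = str(exc)
        _json_dump(artifact, out / f"{method}.json")
        log_lines.append(f"wrote {method}.json")

    if config.report and data is not None:
        rep = tip.comparative_report(
            data, multipliers=tuple(config.multipliers), alpha=config.alpha, seed=config.seed
        )
        _json_dump(rep.to_dict(), out / "comparative_report.json")
        rep.to_frame().to_csv(out / "comparative_report.csv", index=False)
        (out / "comparative_report.md").write_text(rep.to_markdown() + "\n")
        log_lines.append("wrote comparative_report.{json,csv,md}")

    summary_md = [f"# qbalin run ({cfg_hash})", "", f"- seed: {config.seed}",
                  f"- methods: {', '.join(config.methods)}"]
    if errors:
        summary_md.append(f"- errors: {json.dumps(errors)}")
    (out / "summary.md").write_text("\n".join(summary_md) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    if errors:
        _json_dump({"errors": errors}, out / "errors.json")
        return 1
    return 0
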