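"""Serialization and re-analysis of power-analysis results.

A finished run can be written to JSON (configuration, every significance
record, the fitted power curves and the required sample sizes), the records
and the power curve to CSV, and — because the simulated decisions are kept —
re-analyzed for a new target power or confidence level without re-simulating
anything.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .power_model import (
    PowerModelFit,
    SignificanceRecord,
    band_crossing_n,
    fit_power_model,
    predict_power,
    required_n,
    required_n_lb,
)
from .search import MSPEResult, SearchConfig, StepRecord

__all__ = [
    "reanalyze",
    "result_to_json",
    "result_from_json",
    "records_to_csv",
    "power_curve_frame",
    "power_curve_to_csv",
    "step_history_to_csv",
]


def reanalyze(
    result: MSPEResult, rho: float, alpha_rho: float | None = None
) -> MSPEResult:
    """Recompute power fits and required sample sizes for new targets.

    Uses the stored significance records only; nothing is re-simulated.
    """
    cfg = dataclasses.replace(
        result.config,
        rho=rho,
        alpha_rho=result.config.alpha_rho if alpha_rho is None else alpha_rho,
    )
    new = MSPEResult(
        config=cfg,
        pois=list(result.pois),
        records=list(result.records),
        step_history=list(result.step_history),
        performance=result.performance,
    )
    for key in result.pois:
        fit = fit_power_model(result.records, key, cfg.link)
        new.fits[key] = fit
        new.n_alpha[key] = required_n(fit, cfg.rho)
        new.n_alpha_lb[key] = required_n_lb(fit, cfg.rho, cfg.alpha_rho)
        new.n_alpha_lb_exact[key] = band_crossing_n(
            fit, cfg.rho, cfg.alpha_rho, "lower", integer=False
        )
    return new


def _fit_to_dict(fit: PowerModelFit) -> dict:
    return {
        "link": fit.link,
        "beta0": fit.beta0,
        "beta1": fit.beta1,
        "vcov": np.asarray(fit.vcov).tolist(),
        "n_records": fit.n_records,
    }


def _fit_from_dict(d: dict) -> PowerModelFit:
    return PowerModelFit(
        d["link"], d["beta0"], d["beta1"], np.asarray(d["vcov"]), d["n_records"]
    )


def result_to_json(result: MSPEResult, path=None) -> str:
    payload = {
        "config": dataclasses.asdict(result.config),
        "pois": result.pois,
        "records": [
            {"n": r.n, "converged": r.converged, "decisions": r.decisions}
            for r in result.records
        ],
        "fits": {k: _fit_to_dict(f) for k, f in result.fits.items()},
        "n_alpha": result.n_alpha,
        "n_alpha_lb": result.n_alpha_lb,
        "n_alpha_lb_exact": result.n_alpha_lb_exact,
        "overall_n_alpha": result.overall_n_alpha,
        "overall_n_alpha_lb": result.overall_n_alpha_lb,
        "convergence_rate": result.convergence_rate,
        "step_history": [dataclasses.asdict(s) for s in result.step_history],
        "performance": result.performance,
        "wall_time": result.wall_time,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def result_from_json(source) -> MSPEResult:
    if isinstance(source, (str, Path)) and Path(source).exists():
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(source)
    cfg = SearchConfig(**payload["config"])
    result = MSPEResult(
        config=cfg,
        pois=payload["pois"],
        records=[
            SignificanceRecord(r["n"], r["converged"], r["decisions"])
            for r in payload["records"]
        ],
        fits={k: _fit_from_dict(d) for k, d in payload["fits"].items()},
        n_alpha={k: int(v) for k, v in payload["n_alpha"].items()},
        n_alpha_lb={k: int(v) for k, v in payload["n_alpha_lb"].items()},
        n_alpha_lb_exact={
            k: float(v) for k, v in payload.get("n_alpha_lb_exact", {}).items()
        },
        step_history=[StepRecord(**s) for s in payload["step_history"]],
        performance=payload.get("performance"),
        wall_time=payload.get("wall_time", 0.0),
    )
    return result


def records_to_csv(result: MSPEResult, path) -> None:
    rows = []
    for r in result.records:
        row = {"n": r.n, "converged": int(r.converged)}
        for key in result.pois:
            row[f"S[{key}]"] = r.decisions.get(key, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def power_curve_frame(
    result: MSPEResult, n_grid=None, alpha_rho: float | None = None
) -> pd.DataFrame:
    """Power point estimate and confidence band per POI over a grid of n."""
    alpha_rho = result.config.alpha_rho if alpha_rho is None else alpha_rho
    if n_grid is None:
        top = int(1.2 * result.overall_n_alpha_lb)
        lo = min(r.n for r in result.records)
        n_grid = np.unique(np.linspace(max(lo // 2, 2), top, 100).astype(int))
    frames = []
    for key, fit in result.fits.items():
        point, lower, upper = predict_power(fit, np.asarray(n_grid), alpha_rho)
        frames.append(
            pd.DataFrame(
                {
                    "poi": key,
                    "n": n_grid,
                    "power_point": point,
                    "power_lower": lower,
                    "power_upper": upper,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def power_curve_to_csv(result: MSPEResult, path, **kwargs) -> None:
    power_curve_frame(result, **kwargs).to_csv(path, index=False)


def step_history_to_csv(result: MSPEResult, path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in result.step_history]).to_csv(
        path, index=False
    )
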