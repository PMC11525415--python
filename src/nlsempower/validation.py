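"""Monte-Carlo evaluation of search algorithms and estimators.

``evaluate_search`` repeats a full power-analysis run many times against a
known reference required sample size and summarizes how the conservative
estimate :math:`\\hat N_{\\alpha,\\mathrm{lb}}` behaves:

.. math::

    \\mathrm{Bias} = \\tfrac1R \\sum_i \\hat N_{\\mathrm{lb},i} - N_\\alpha,
    \\quad
    \\mathrm{RMSE} = \\sqrt{\\tfrac1R \\sum_i (\\hat N_{\\mathrm{lb},i} - N_\\alpha)^2},
    \\quad
    \\mathrm{Type\\ I} = \\tfrac1R \\sum_i 1\\{\\hat N_{\\mathrm{lb},i} < N_\\alpha\\}.

By construction the lower-bound estimate is conservative, so its bias should
be small and positive and the Type I rate close to
:math:`\\alpha_\\rho/2`.

``estimator_performance`` aggregates a batch of QISEM fits into sample-size
weighted parameter bias, relative bias, root weighted MSE and the
convergence rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import FitResult
from .model_syntax import ModelSpec
from .search import SearchConfig, run_adaptive, run_brute_force

__all__ = [
    "PerformanceSummary",
    "EstimatorPerformance",
    "summarize_nlb",
    "evaluate_search",
    "estimator_performance",
]


@dataclass
class PerformanceSummary:
    """Bias / relative bias / RMSE / Type I of the required-sample-size estimate.

    Bias, relative bias and RMSE describe the integer recommendation (the
    ceiling of the inverted lower confidence band).  The Type I rate — how
    often the estimate falls below the reference — is evaluated on the
    *continuous* band inversion: the rounding step makes the integer
    indicator artificially conservative whenever one unit of n moves the
    power by a non-negligible fraction of its standard error (small required
    sizes), while the continuous crossing carries the nominal confidence
    level.  ``type1_integer`` reports the rounded version alongside.
    """

    bias: float
    relative_bias: float
    rmse: float
    type1: float
    type1_integer: float
    reps: int
    failed: int
    n_alpha_ref: float
    estimates: list[int] = field(default_factory=list)
    exact_estimates: list[float] = field(default_factory=list)


@dataclass
class EstimatorPerformance:
    """Sample-size weighted parameter recovery of a batch of QISEM fits."""

    w_bias: float
    w_rel_bias: float  # percent
    rw_mse: float
    convergence: float
    per_parameter: dict[str, dict[str, float]] = field(default_factory=dict)


def summarize_nlb(
    estimates: list[int],
    n_alpha_ref: float,
    failed: int = 0,
    exact_estimates: list[float] | None = None,
) -> PerformanceSummary:
    arr = np.asarray(estimates, dtype=float)
    dev = arr - n_alpha_ref
    exact = (
        np.asarray(exact_estimates, dtype=float)
        if exact_estimates is not None
        else arr
    )
    return PerformanceSummary(
        bias=float(dev.mean()),
        relative_bias=float(dev.mean() / n_alpha_ref),
        rmse=float(np.sqrt((dev**2).mean())),
        type1=float((exact < n_alpha_ref).mean()),
        type1_integer=float((arr < n_alpha_ref).mean()),
        reps=len(estimates),
        failed=failed,
        n_alpha_ref=n_alpha_ref,
        estimates=[int(v) for v in estimates],
        exact_estimates=[float(v) for v in exact],
    )


def evaluate_search(
    backend_factory,
    config: SearchConfig,
    reps: int,
    n_alpha_ref: int,
    seed: int,
) -> PerformanceSummary:
    """Run the configured search ``reps`` times on fresh decisions.

    ``backend_factory`` is a zero-argument callable returning a fresh backend
    (typically :func:`~nlsempower.search.make_artificial_backend`).  Repeats
    whose final power fit fails (separation) are counted, not silently
    dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    estimates: list[int] = []
    exact: list[float] = []
    failed = 0
    from .simulate import child_seeds

    rep_seeds = child_seeds(seed, reps)
    for rep_seed in rep_seeds:
        backend = backend_factory()
        cfg = SearchConfig(**{**config.__dict__, "seed": rep_seed})
        try:
            if cfg.method == "adaptive":
                result = run_adaptive(backend, cfg)
            else:
                result = run_brute_force(backend, cfg)
            estimates.append(result.overall_n_alpha_lb)
            exact.append(result.overall_n_alpha_lb_exact)
        except RuntimeError:
            failed += 1
    if not estimates:
        raise RuntimeError("every repeat failed; no summary available")
    return summarize_nlb(estimates, n_alpha_ref, failed, exact)


def estimator_performance(
    fits: list[FitResult], spec: ModelSpec
) -> EstimatorPerformance:
    """Sample-size weighted bias / relative bias / root weighted MSE.

    Per structural parameter, over converged fits with weights :math:`n_i`:
    ``wBias = sum n_i (est_i - pop) / sum n_i`` and
    ``rwMSE = sqrt(sum n_i (est_i - pop)^2 / sum n_i)``; the relative bias
    divides by the population value (parameters with population value 0 are
    excluded from the relative average).  Scalars are unweighted means over
    the structural coefficients; convergence is converged / total.
    """
    total = len(fits)
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to summarize")
    params = [
        (f"{lhs}~{term}", value)
        for lhs, terms in spec.equations.items()
        for term, value in terms
    ]
    per_param: dict[str, dict[str, float]] = {}
    biases, rel_biases, rmses = [], [], []
    for key, pop in params:
        usable = [(f.n, f.estimates[key]) for f in converged if key in f.estimates]
        if not usable:
            continue
        w = np.array([n for n, _ in usable], dtype=float)
        est = np.array([e for _, e in usable])
        w_bias = float(np.sum(w * (est - pop)) / w.sum())
        rw_mse = float(np.sqrt(np.sum(w * (est - pop) ** 2) / w.sum()))
        entry = {"wBias": w_bias, "rwMSE": rw_mse, "population": pop}
        biases.append(w_bias)
        rmses.append(rw_mse)
        if pop != 0:
            entry["wRelBias"] = 100.0 * w_bias / pop
            rel_biases.append(entry["wRelBias"])
        per_param[key] = entry
    return EstimatorPerformance(
        w_bias=float(np.mean(biases)),
        w_rel_bias=float(np.mean(rel_biases)) if rel_biases else float("nan"),
        rw_mse=float(np.mean(rmses)),
        convergence=len(converged) / total,
        per_parameter=per_param,
    )
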