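"""Selection of replication sample sizes: brute force and adaptive search.

The brute-force driver draws all ``R`` sample sizes up front from a
user-given interval (systematically or at random) and fits the power model
once.  The adaptive driver spends the ``R`` replications over several steps:
a *wide* phase keeps the drawn sizes inside the sample-size window whose
predicted power lies in [.15, .85] (the information-rich part of the curve,
steepest around power .5), then a *narrow* phase concentrates them around
the target power, inside the window where the confidence band brackets the
target.  Every step refits the power curve on all accumulated records, and
interval endpoints can be constrained to change by at most a factor per step
so a bad early fit cannot throw the search.

Both drivers take a *backend* that maps one sample size to one significance
record.  The model-based backend simulates a dataset and fits the QISEM; the
artificial backend draws decisions directly from a known probit curve and is
the vehicle for validating the search machinery itself.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .estimators import fit_qisem
from .model_syntax import ModelSpec, ParameterRef, count_parameters
from .power_model import (
    PowerModelFit,
    SeparationError,
    SignificanceRecord,
    band_crossing_n,
    fit_power_model,
    predict_power,
    required_n,
    required_n_lb,
    significance_decisions,
)
from .simulate import child_seeds, simulate_dataset

__all__ = [
    "SearchConfig",
    "StepRecord",
    "MSPEResult",
    "allocate_replications",
    "draw_sizes",
    "run_brute_force",
    "run_adaptive",
    "run_mspe",
    "make_artificial_backend",
    "QisemBackend",
    "ArtificialBackend",
]

CHANGE_FACTOR = 2.0  # max per-step relative change of interval endpoints


@dataclass
class SearchConfig:
    """Hyperparameters of the sample-size search."""

    method: str = "adaptive"  # adaptive | bruteforce
    R: int = 2000
    steps: int = 10
    switch_step: int | None = None  # default steps // 2
    n_start: int | None = None  # default 10 * #par
    n_lb: int | None = None  # default 5 * #par
    dist_rj: str = "increasing"  # equal | increasing | u_shaped
    constrain_change: bool = True
    n_min: int | None = None  # brute force interval
    n_max: int | None = None
    draw: str = "systematic"  # systematic | random (brute force)
    grid_replicates: int = 1  # systematic draws per grid point
    rho: float = 0.8
    alpha: float = 0.05
    alpha_rho: float = 0.05
    test: str = "onesided"
    link: str = "probit"
    seed: int = 0
    cores: int = 1

    def resolved(self, n_par: int | None = None) -> "SearchConfig":
        cfg = replace(self)
        if cfg.switch_step is None:
            cfg.switch_step = max(cfg.steps // 2, 2)
        if cfg.n_start is None and cfg.method == "adaptive":
            if n_par is None:
                raise ValueError("n_start not set and no parameter count given")
            cfg.n_start = 10 * n_par
        if cfg.n_lb is None:
            cfg.n_lb = 5 * n_par if n_par is not None else 1
        if cfg.R < cfg.steps:
            raise ValueError("R must be at least the number of steps")
        if cfg.n_lb < 1:
            raise ValueError("n_lb must be >= 1")
        if cfg.method == "bruteforce":
            if cfg.n_min is None or cfg.n_max is None:
                raise ValueError("brute force requires n_min and n_max")
            if cfg.n_min >= cfg.n_max:
                raise ValueError("n_min must be smaller than n_max")
        if cfg.dist_rj not in ("equal", "increasing", "u_shaped"):
            raise ValueError(f"unknown distRj {cfg.dist_rj!r}")
        return cfg


@dataclass
class StepRecord:
    """Bookkeeping of one adaptive step."""

    step: int
    n_min: int
    n_max: int
    r_j: int
    beta0: float | None = None
    beta1: float | None = None
    interim_n_alpha: int | None = None


@dataclass
class MSPEResult:
    """Everything a power analysis run produces."""

    config: SearchConfig
    pois: list[str]
    records: list[SignificanceRecord]
    fits: dict[str, PowerModelFit] = field(default_factory=dict)
    n_alpha: dict[str, int] = field(default_factory=dict)
    n_alpha_lb: dict[str, int] = field(default_factory=dict)
    n_alpha_lb_exact: dict[str, float] = field(default_factory=dict)
    step_history: list[StepRecord] = field(default_factory=list)
    performance: dict | None = None
    wall_time: float = 0.0

    @property
    def overall_n_alpha(self) -> int:
        return max(self.n_alpha.values())

    @property
    def overall_n_alpha_lb(self) -> int:
        return max(self.n_alpha_lb.values())

    @property
    def overall_n_alpha_lb_exact(self) -> float:
        return max(self.n_alpha_lb_exact.values())

    @property
    def convergence_rate(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r.converged for r in self.records) / len(self.records)


def allocate_replications(R: int, steps: int, dist_rj: str) -> list[int]:
    """Split ``R`` replications over ``steps`` according to the chosen shape.

    ``equal`` gives floor(R/steps) each; ``increasing`` is proportional to the
    step index; ``u_shaped`` to ``1 + |j - (steps+1)/2|``.  Rounding remainders
    go to the last step so the total is exactly ``R``.
    """
    if R < steps:
        raise ValueError("R must be at least the number of steps")
    if dist_rj == "equal":
        weights = np.ones(steps)
    elif dist_rj == "increasing":
        weights = np.arange(1, steps + 1, dtype=float)
    elif dist_rj == "u_shaped":
        j = np.arange(1, steps + 1, dtype=float)
        weights = 1.0 + np.abs(j - (steps + 1) / 2.0)
    else:
        raise ValueError(f"unknown distRj {dist_rj!r}")
    raw = np.maximum(np.floor(R * weights / weights.sum()).astype(int), 1)
    raw[-1] += R - raw.sum()
    if raw[-1] < 1:  # pathological tiny R: rebalance
        raw = np.maximum(raw, 1)
        while raw.sum() > R:
            raw[np.argmax(raw)] -= 1
    return raw.tolist()


def draw_sizes(
    interval: tuple[int, int], count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform integer draws on ``[n_min, n_max]`` (symmetric about the middle)."""
    n_min, n_max = int(interval[0]), int(interval[1])
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    if n_min == n_max:
        return np.full(count, n_min, dtype=int)
    return rng.integers(n_min, n_max + 1, size=count)


# ---------------------------------------------------------------------------
# backends


class ArtificialBackend:
    """Draws significance decisions directly from a known probit power curve.

    ``S ~ Bernoulli(Phi(beta0 + beta1 sqrt(n)))`` — the stand-in for a full
    simulate-and-fit cycle when the search machinery itself is under study.
    """

    poi_key = "artificial"

    def __init__(self, beta0: float, beta1: float):
        self.beta0 = beta0
        self.beta1 = beta1

    @property
    def poi_keys(self) -> list[str]:
        return [self.poi_key]

    def success_probability(self, n) -> np.ndarray:
        from scipy.stats import norm

        return norm.cdf(self.beta0 + self.beta1 * np.sqrt(np.asarray(n, float)))

    def evaluate(
        self, sizes: np.ndarray, seeds: list[int], cores: int = 1
    ) -> list[SignificanceRecord]:
        # one cheap Bernoulli per replication: a single batch stream keyed by
        # the replication seeds (this backend is never run multi-core)
        p = self.success_probability(sizes)
        u = np.random.default_rng(list(seeds)).random(len(p))
        return [
            SignificanceRecord(int(n), True, {self.poi_key: int(ui < pi)})
            for n, pi, ui in zip(sizes, p, u)
        ]


def make_artificial_backend(beta0: float, beta1: float) -> ArtificialBackend:
    return ArtificialBackend(beta0, beta1)


class QisemBackend:
    """Simulate a dataset from the population model and fit it."""

    def __init__(
        self,
        spec: ModelSpec,
        estimator: str,
        pois: list[ParameterRef],
        alpha: float,
        test: str,
        **estimator_options,
    ):
        self.spec = spec
        self.estimator = estimator
        self.pois = pois
        self.alpha = alpha
        self.test = test
        self.options = estimator_options

    @property
    def poi_keys(self) -> list[str]:
        return [str(p) for p in self.pois]

    def _one(self, n: int, seed: int) -> SignificanceRecord:
        sample = simulate_dataset(self.spec, int(n), seed)
        fit = fit_qisem(sample, self.spec, self.estimator, **self.options)
        return significance_decisions(
            [fit], self.pois, self.alpha, self.test, self.spec
        )[0]

    def evaluate(
        self, sizes: np.ndarray, seeds: list[int], cores: int = 1
    ) -> list[SignificanceRecord]:
        if cores > 1 and len(sizes) > 1:
            from joblib import Parallel, delayed

            return Parallel(n_jobs=cores)(
                delayed(self._one)(n, s) for n, s in zip(sizes, seeds)
            )
        return [self._one(n, s) for n, s in zip(sizes, seeds)]


# ---------------------------------------------------------------------------
# drivers


def _decisive_fit(
    records: list[SignificanceRecord], poi_keys: list[str], link: str, rho: float
) -> tuple[dict[str, PowerModelFit], str]:
    """Fit all POIs; the decisive one needs the largest n at the target power."""
    fits = {key: fit_power_model(records, key, link) for key in poi_keys}
    for key, fit in fits.items():
        if fit.beta1 <= 0:
            raise SeparationError(
                f"power curve for {key} has non-positive slope on the current "
                f"records; widen the range of sample sizes"
            )
    decisive = max(poi_keys, key=lambda k: required_n(fits[k], rho))
    return fits, decisive


def _finalize(
    result: MSPEResult, backend, records: list[SignificanceRecord], cfg: SearchConfig
) -> MSPEResult:
    fits, _ = _decisive_fit(records, backend.poi_keys, cfg.link, cfg.rho)
    for key, fit in fits.items():
        result.fits[key] = fit
        result.n_alpha[key] = required_n(fit, cfg.rho)
        result.n_alpha_lb[key] = required_n_lb(fit, cfg.rho, cfg.alpha_rho)
        result.n_alpha_lb_exact[key] = band_crossing_n(
            fit, cfg.rho, cfg.alpha_rho, "lower", integer=False
        )
    return result


def run_brute_force(backend, config: SearchConfig) -> MSPEResult:
    """A-priori sample sizes on ``[n_min, n_max]``, one final power fit."""
    t0 = time.perf_counter()
    cfg = config.resolved()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    if cfg.draw == "systematic":
        k = max(cfg.R // cfg.grid_replicates, 1)
        grid = np.unique(np.round(np.linspace(cfg.n_min, cfg.n_max, k)).astype(int))
        sizes = np.repeat(grid, cfg.grid_replicates)
        if sizes.size < cfg.R:  # rounding collapsed grid points: pad randomly
            extra = draw_sizes((cfg.n_min, cfg.n_max), cfg.R - sizes.size, rng)
            sizes = np.concatenate([sizes, extra])
        sizes = sizes[: cfg.R]
    elif cfg.draw == "random":
        sizes = draw_sizes((cfg.n_min, cfg.n_max), cfg.R, rng)
    else:
        raise ValueError(f"unknown draw {cfg.draw!r}")
    sizes = np.maximum(sizes, cfg.n_lb)
    seeds = child_seeds(cfg.seed, len(sizes))
    records = backend.evaluate(sizes, seeds, cfg.cores)
    result = MSPEResult(cfg, backend.poi_keys, records)
    result.step_history.append(
        StepRecord(1, int(sizes.min()), int(sizes.max()), len(sizes))
    )
    result = _finalize(result, backend, records, cfg)
    result.wall_time = time.perf_counter() - t0
    return result


def run_adaptive(backend, config: SearchConfig, n_par: int | None = None) -> MSPEResult:
    """Wide-to-narrow adaptive selection of the replication sample sizes."""
    t0 = time.perf_counter()
    cfg = config.resolved(n_par)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    r_j = allocate_replications(cfg.R, cfg.steps, cfg.dist_rj)
    records: list[SignificanceRecord] = []
    history: list[StepRecord] = []
    seeds = child_seeds(cfg.seed, cfg.R)
    used = 0
    prev_lo = lo = max(cfg.n_start // 2, cfg.n_lb, 1)
    prev_hi = hi = max(2 * cfg.n_start, lo)
    fell_back = False

    for j in range(1, cfg.steps + 1):
        if j > 1:
            try:
                fits, decisive = _decisive_fit(
                    records, backend.poi_keys, cfg.link, cfg.rho
                )
                fit = fits[decisive]
                if j < cfg.switch_step:  # wide search
                    cand_lo = required_n(fit, 0.15)
                    cand_hi = required_n(fit, 0.85)
                else:  # narrow search around the target power
                    try:
                        cand_lo = band_crossing_n(fit, cfg.rho, cfg.alpha_rho, "upper")
                        cand_hi = band_crossing_n(fit, cfg.rho, cfg.alpha_rho, "lower")
                    except RuntimeError:
                        cand_lo = required_n(fit, 0.15)
                        cand_hi = required_n(fit, 0.85)
                if cfg.constrain_change:
                    step_lb = int(np.floor(prev_lo / CHANGE_FACTOR))
                    step_ub = int(np.ceil(prev_hi * CHANGE_FACTOR))
                else:
                    step_lb, step_ub = 1, 10**9
                lo = max(cand_lo, step_lb, cfg.n_lb, 1)
                hi = min(cand_hi, step_ub)
                if hi < lo:
                    hi = lo
                fell_back = False
                interim = (fit.beta0, fit.beta1, required_n(fit, cfg.rho))
            except SeparationError:
                # widen: double the previous interval and try again next step
                lo = max(int(prev_lo / 2), cfg.n_lb, 1)
                hi = max(prev_hi * 2, lo)
                fell_back = True
                interim = (None, None, None)
        else:
            interim = (None, None, None)
        sizes = draw_sizes((lo, hi), r_j[j - 1], rng)
        step_seeds = seeds[used : used + len(sizes)]
        used += len(sizes)
        records.extend(backend.evaluate(sizes, step_seeds, cfg.cores))
        history.append(StepRecord(j, int(lo), int(hi), len(sizes), *interim))
        prev_lo, prev_hi = lo, hi

    result = MSPEResult(cfg, backend.poi_keys, records, step_history=history)
    result = _finalize(result, backend, records, cfg)  # may raise SeparationError
    result.wall_time = time.perf_counter() - t0
    return result


def run_mspe(
    spec: ModelSpec,
    pois: list[ParameterRef | str],
    estimator: str = "SR",
    config: SearchConfig | None = None,
    **estimator_options,
) -> MSPEResult:
    """End-to-end power analysis: simulate, fit, decide, search, invert."""
    cfg = config or SearchConfig()
    pois = [p if isinstance(p, ParameterRef) else ParameterRef.parse(p) for p in pois]
    for p in pois:
        try:
            spec.coefficient(p)
        except KeyError:
            available = [
                f"{lhs}~{t}" for lhs, ts in spec.equations.items() for t, _ in ts
            ]
            raise KeyError(
                f"POI {p} does not name a structural coefficient; available: "
                + ", ".join(available)
            ) from None
    backend = QisemBackend(spec, estimator, pois, cfg.alpha, cfg.test, **estimator_options)
    n_par = count_parameters(spec, estimator)
    if cfg.method == "adaptive":
        return run_adaptive(backend, cfg, n_par)
    if cfg.method == "bruteforce":
        return run_brute_force(backend, cfg.resolved(n_par))
    raise ValueError(f"unknown search method {cfg.method!r}")
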