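"""Equation-by-equation simulation of indicator data from a population QISEM.

Exogenous latents, structural residuals and measurement errors are drawn
jointly multivariate normal from their declared (co)variances.  Endogenous
latents are then built constructively in topological order as coefficient-
weighted sums of their terms — products formed from the realized values — plus
the residual.  Indicators are ``intercept + loading * latent + error``.  The
endogenous side is therefore model-implied non-normal whenever the structural
equation contains product terms.

Reproducibility contract: a dataset is a pure function of ``(spec, n, seed)``;
batches derive one independent substream per element from ``(seed, index)`` so
that results do not depend on execution order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_syntax import ModelSpec

__all__ = ["Sample", "simulate_dataset", "simulate_batch", "child_seeds"]


@dataclass
class Sample:
    """One simulated dataset: an ``n x p`` indicator matrix plus provenance."""

    data: pd.DataFrame
    seed: int

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _joint_normal_draw(spec: ModelSpec, n: int, rng: np.random.Generator):
    """Draw exogenous latents, residuals and errors as one centered MVN block."""
    exo = spec.exogenous
    endo = spec.endogenous
    errs = [
        name
        for lat in spec.latents
        for name, _ in spec.measurement.get(lat, [])
    ]
    names = exo + endo + errs  # residual of endo latent keyed by its name
    p = len(names)
    cov = np.zeros((p, p))
    idx = {name: i for i, name in enumerate(names)}
    for i, a in enumerate(names):
        cov[i, i] = spec.variance(a, a)
    for (a, b), v in spec.variances.items():
        if a != b and a in idx and b in idx:
            # covariances are supported within a block (exogenous latents,
            # residuals, or errors); cross-block entries were rejected upstream
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = v
    # allow exactly-zero variances (degenerate measurement) by using the
    # Cholesky factor of the positive-semidefinite matrix via eigen decomposition
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, p))
    draws = z @ root.T
    return {name: draws[:, idx[name]] for name in names}


def simulate_dataset(spec: ModelSpec, n: int, seed: int) -> Sample:
    """Simulate an indicator-level dataset of size `n` from the population model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = _joint_normal_draw(spec, n, rng)

    latent_values: dict[str, np.ndarray] = {}
    for name in spec.exogenous:
        latent_values[name] = draws[name] + spec.mean(name)
    for lhs in spec.topological_order():
        if lhs in latent_values:
            continue
        total = draws[lhs] + spec.mean(lhs)  # residual + intercept
        for term, gamma in spec.equations[lhs]:
            factor = latent_values[term.variables[0]].copy()
            for v in term.variables[1:]:
                factor *= latent_values[v]
            total = total + gamma * factor
        latent_values[lhs] = total

    columns: dict[str, np.ndarray] = {}
    for lat in spec.latents:
        inds = spec.measurement.get(lat, [])
        if not inds:
            columns[lat] = latent_values[lat]
            continue
        for name, loading in inds:
            columns[name] = (
                spec.mean(name) + loading * latent_values[lat] + draws[name]
            )
    frame = pd.DataFrame({name: columns[name] for name in spec.indicators})
    return Sample(data=frame, seed=seed)


def child_seeds(seed: int, count: int) -> list[int]:
    """Deterministic independent substream seeds derived from ``(seed, index)``.

    Seed ``i`` is the ``i``-th word of the master seed's entropy stream, so it
    depends only on ``(seed, i)`` — results are reproducible regardless of
    batch size, execution order or parallelism.
    """
    if seed is None:
        raise ValueError("a master seed is required")
    words = np.random.SeedSequence(seed).generate_state(count, np.uint32)
    return [int(w) % (2**31) for w in words]


def simulate_batch(spec: ModelSpec, sizes: list[int], seed: int) -> list[Sample]:
    """One independent sample per requested size, reproducible element-wise."""
    if not sizes:
        raise ValueError("sizes must be nonempty")
    seeds = child_seeds(seed, len(sizes))
    return [simulate_dataset(spec, n, s) for n, s in zip(sizes, seeds)]
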