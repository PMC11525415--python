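"""Estimators for quadratic/interaction SEM: SR, FSR and UPI.

Three routes from one simulated dataset to structural-coefficient estimates
with heteroskedasticity-robust standard errors:

``SR``
    Scale regression — the mean over each latent's indicators is used as a
    single proxy; nonlinear regressors are products of the *centered* scale
    means; the recursive path model is fitted equation by equation by least
    squares with HC1 sandwich standard errors.  Simple, but measurement error
    is unmodeled, so product coefficients are attenuated.

``FSR``
    Factor score regression — a linear confirmatory factor model is fitted by
    ML; *regression* (Thomson) scores estimate the exogenous latents and
    *Bartlett* scores the endogenous ones; centered scores and their products
    enter the same path regression.

``UPI``
    Unconstrained product indicators — products of indicators measure each
    latent product factor; the augmented *linear* SEM (all loadings, error
    variances and latent (co)variances free) is fitted by ML with sandwich
    standard errors.

``LMS`` is recognized but refused: it needs an external Mplus installation
and is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_syntax import ModelSpec, ParameterRef, Term
from .sem import SemTemplate, fit_linear_sem
from .simulate import Sample

__all__ = [
    "FitResult",
    "fit_sr",
    "fit_fsr",
    "fit_upi",
    "fit_qisem",
    "build_product_indicators",
    "matched_product_indicator_count",
    "product_indicator_pairs",
    "METHODS",
]

METHODS = ("SR", "FSR", "UPI")


@dataclass
class FitResult:
    """Parameter estimates and robust standard errors from one fitted sample."""

    method: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    n: int

    def resolve(self, poi: ParameterRef) -> tuple[float, float]:
        key = str(poi)
        if key not in self.estimates:
            raise KeyError(
                f"parameter {key!r} not found; available: "
                + ", ".join(sorted(self.estimates))
            )
        return self.estimates[key], self.standard_errors[key]


def _failed(method: str, n: int) -> FitResult:
    return FitResult(method, {}, {}, False, n)


# ---------------------------------------------------------------------------
# path-model machinery shared by SR and FSR


def _path_model(
    method: str,
    values: dict[str, np.ndarray],
    spec: ModelSpec,
    n: int,
) -> FitResult:
    """Recursive path model on (centered) proxy variables, HC1 errors."""
    centered = {k: v - v.mean() for k, v in values.items()}
    estimates: dict[str, float] = {}
    ses: dict[str, float] = {}
    for lhs, terms in spec.equations.items():
        y = values[lhs]
        cols = []
        for term, _ in terms:
            col = centered[term.variables[0]].copy()
            for v in term.variables[1:]:
                col = col * centered[v]
            cols.append(col)
        x = np.column_stack([np.ones(n)] + cols)
        if n <= x.shape[1] or np.linalg.matrix_rank(x) < x.shape[1]:
            return _failed(method, n)
        fit = sm.OLS(y, x).fit(cov_type="HC1")
        estimates[f"{lhs}~1"] = float(fit.params[0])
        ses[f"{lhs}~1"] = float(fit.bse[0])
        for (term, _), b, se in zip(terms, fit.params[1:], fit.bse[1:]):
            estimates[f"{lhs}~{term}"] = float(b)
            ses[f"{lhs}~{term}"] = float(se)
        resid_var = float(fit.resid @ fit.resid / (n - x.shape[1]))
        estimates[f"{lhs}~~{lhs}"] = resid_var
        ses[f"{lhs}~~{lhs}"] = resid_var * np.sqrt(2.0 / max(n - x.shape[1], 1))
    if not all(np.isfinite(list(ses.values()))) or min(ses.values()) <= 0:
        return _failed(method, n)
    return FitResult(method, estimates, ses, True, n)


def fit_sr(sample: Sample, spec: ModelSpec) -> FitResult:
    """Scale regression: scale means as single indicators in a path model."""
    data = sample.data
    scales: dict[str, np.ndarray] = {}
    for lat in spec.latents:
        names = spec.indicator_names(lat)
        block = data[names].to_numpy()
        if np.any(block.std(axis=0) == 0):
            return _failed("SR", sample.n)  # degenerate (constant) indicator
        scales[lat] = block.mean(axis=1)
    if any(np.std(v) == 0 for v in scales.values()):
        return _failed("SR", sample.n)
    return _path_model("SR", scales, spec, sample.n)


# ---------------------------------------------------------------------------
# factor score regression


def _cfa_template(spec: ModelSpec) -> SemTemplate:
    """Linear measurement model: marker loading 1, full free latent covariance.

    Single-indicator latents are not identified with a free error variance, so
    their loading and error variance are fixed at the declared population
    values.
    """
    obs, lats = [], []
    loadings: dict[tuple[str, str], float | str] = {}
    theta: dict[tuple[str, str], float | str] = {}
    psi: dict[tuple[str, str], float | str] = {}
    for lat in spec.latents:
        inds = spec.measurement.get(lat, [])
        lats.append(lat)
        if not inds:  # directly observed: identity measurement
            obs.append(lat)
            loadings[(lat, lat)] = 1.0
            theta[(lat, lat)] = 0.0
            continue
        if len(inds) == 1:
            name, lam = inds[0]
            obs.append(name)
            loadings[(name, lat)] = float(lam)
            theta[(name, name)] = float(spec.variance(name))
            continue
        for i, (name, _) in enumerate(inds):
            obs.append(name)
            loadings[(name, lat)] = 1.0 if i == 0 else "free"
            theta[(name, name)] = "free"
    for i, a in enumerate(lats):
        for b in lats[i:]:
            psi[tuple(sorted((a, b)))] = "free"
    return SemTemplate(obs, lats, loadings, [], psi, theta)


def _score_matrices(template: SemTemplate, estimates: dict[str, float]):
    p, m = len(template.obs_names), len(template.latent_names)
    lam = np.zeros((p, m))
    th = np.zeros(p)
    phi = np.zeros((m, m))
    oi = {n: i for i, n in enumerate(template.obs_names)}
    li = {n: i for i, n in enumerate(template.latent_names)}
    for (ind, lat), v in template.loadings.items():
        key = f"{lat}=~{ind}"
        lam[oi[ind], li[lat]] = estimates.get(key, v if v != "free" else 0.0)
    for (a, b), v in template.theta.items():
        key = f"{min(a,b)}~~{max(a,b)}"
        if a == b:
            th[oi[a]] = estimates.get(key, v if v != "free" else 0.0)
    for (a, b), v in template.psi.items():
        key = f"{min(a,b)}~~{max(a,b)}"
        val = estimates.get(key, v if v != "free" else 0.0)
        phi[li[a], li[b]] = phi[li[b], li[a]] = val
    return lam, th, phi


def fit_fsr(sample: Sample, spec: ModelSpec) -> FitResult:
    """Factor score regression, SL flavor: regression scores for exogenous,
    Bartlett scores for endogenous latents, then a robust path regression."""
    template = _cfa_template(spec)
    cfa = fit_linear_sem(sample.data, template)
    if not cfa.converged:
        return _failed("FSR", sample.n)
    lam, th, phi = _score_matrices(template, cfa.estimates)
    x = sample.data[template.obs_names].to_numpy()
    z = x - x.mean(axis=0)
    sigma = lam @ phi @ lam.T + np.diag(th)
    try:
        reg_w = phi @ lam.T @ np.linalg.inv(sigma)  # m x p, Thomson
        th_inv = 1.0 / np.maximum(th, 1e-10)
        a = lam.T * th_inv  # m x p
        bart_w = np.linalg.solve(a @ lam, a)  # Bartlett
    except np.linalg.LinAlgError:
        return _failed("FSR", sample.n)
    reg_scores = z @ reg_w.T
    bart_scores = z @ bart_w.T
    li = {n: i for i, n in enumerate(template.latent_names)}
    endo = set(spec.endogenous)
    values = {
        lat: (bart_scores if lat in endo else reg_scores)[:, li[lat]]
        for lat in spec.latents
    }
    return _path_model("FSR", values, spec, sample.n)


# ---------------------------------------------------------------------------
# unconstrained product indicators


def product_indicator_pairs(
    spec: ModelSpec, term: Term, matching: str = "matched"
) -> list[tuple[str, str]]:
    """Indicator pairs measuring one latent product factor.

    ``matched`` pairs the i-th indicator of each component in declaration
    order (squares of each indicator for quadratic terms); ``all`` takes the
    full cross product.
    """
    a, b = term.variables
    ia = spec.indicator_names(a)
    ib = spec.indicator_names(b)
    if matching == "matched":
        if term.is_quadratic:
            return [(x, x) for x in ia]
        return list(zip(ia, ib))
    if matching == "all":
        if term.is_quadratic:
            return [(ia[i], ia[j]) for i in range(len(ia)) for j in range(i, len(ia))]
        return [(x, y) for x in ia for y in ib]
    raise ValueError(f"unknown matching {matching!r}")


def matched_product_indicator_count(spec: ModelSpec, term: Term) -> int:
    return len(product_indicator_pairs(spec, term, "matched"))


def _pi_name(x: str, y: str) -> str:
    return f"{x}.{y}"


def _product_latent_name(term: Term) -> str:
    return ".".join(term.variables)


def build_product_indicators(
    sample: Sample,
    spec: ModelSpec,
    matching: str = "matched",
    centering: str = "double_mean",
) -> Sample:
    """Append product-indicator columns for every latent product term.

    ``double_mean`` centering centers the two components, forms the product
    and re-centers the product — removing the mean structure of the augmented
    model.  ``mean`` centers only the components; ``none`` multiplies the raw
    columns.
    """
    if centering not in ("double_mean", "mean", "none"):
        raise ValueError(f"unknown centering {centering!r}")
    data = sample.data.copy()
    for term in spec.product_terms():
        for x, y in product_indicator_pairs(spec, term, matching):
            cx = data[x].to_numpy()
            cy = data[y].to_numpy()
            if centering in ("double_mean", "mean"):
                cx = cx - cx.mean()
                cy = cy - cy.mean()
            prod = cx * cy
            if centering == "double_mean":
                prod = prod - prod.mean()
            data[_pi_name(x, y)] = prod
    return Sample(data=data, seed=sample.seed)


def _upi_template(spec: ModelSpec, matching: str) -> SemTemplate:
    obs: list[str] = []
    lats: list[str] = []
    loadings: dict[tuple[str, str], float | str] = {}
    theta: dict[tuple[str, str], float | str] = {}
    psi: dict[tuple[str, str], float | str] = {}
    structural: list[tuple[str, str]] = []

    for lat in spec.latents:
        inds = spec.measurement.get(lat, [])
        lats.append(lat)
        if not inds:
            obs.append(lat)
            loadings[(lat, lat)] = 1.0
            theta[(lat, lat)] = 0.0
            continue
        for i, (name, _) in enumerate(inds):
            obs.append(name)
            loadings[(name, lat)] = 1.0 if i == 0 else "free"
            theta[(name, name)] = "free"

    products = spec.product_terms()
    for term in products:
        plat = _product_latent_name(term)
        lats.append(plat)
        for i, (x, y) in enumerate(product_indicator_pairs(spec, term, matching)):
            name = _pi_name(x, y)
            obs.append(name)
            loadings[(name, plat)] = 1.0 if i == 0 else "free"
            theta[(name, name)] = "free"

    endo = set(spec.endogenous)
    source = [lat for lat in spec.latents if lat not in endo]
    source += [_product_latent_name(t) for t in products]
    for i, a in enumerate(source):
        for b in source[i:]:
            psi[tuple(sorted((a, b)))] = "free"
    for lat in endo:
        psi[(lat, lat)] = "free"
    for lhs, terms in spec.equations.items():
        for term, _ in terms:
            rhs = (
                _product_latent_name(term) if term.is_product else term.variables[0]
            )
            structural.append((lhs, rhs))
    return SemTemplate(obs, lats, loadings, structural, psi, theta)


def fit_upi(
    sample: Sample,
    spec: ModelSpec,
    matching: str = "matched",
    centering: str = "double_mean",
) -> FitResult:
    """Unconstrained product indicator estimation of the QISEM."""
    augmented = build_product_indicators(sample, spec, matching, centering)
    template = _upi_template(spec, matching)
    fit = fit_linear_sem(augmented.data, template)
    if not fit.converged:
        return _failed("UPI", sample.n)
    estimates: dict[str, float] = {}
    ses: dict[str, float] = {}
    plat_to_term = {_product_latent_name(t): t for t in spec.product_terms()}
    for key, value in fit.estimates.items():
        se = fit.standard_errors[key]
        if "~" in key and "~~" not in key and "=~" not in key:
            lhs, rhs = key.split("~")
            term = plat_to_term.get(rhs)
            key = f"{lhs}~{term}" if term is not None else key
        estimates[key] = value
        ses[key] = se
    return FitResult("UPI", estimates, ses, True, sample.n)


def fit_qisem(sample: Sample, spec: ModelSpec, method: str, **options) -> FitResult:
    """Dispatch one sample to the requested estimation method."""
    method = method.upper()
    if method == "SR":
        return fit_sr(sample, spec)
    if method == "FSR":
        return fit_fsr(sample, spec)
    if method == "UPI":
        return fit_upi(sample, spec, **options)
    if method == "LMS":
        raise NotImplementedError(
            "LMS estimation requires an external Mplus installation and is "
            "out of scope; use SR, FSR or UPI"
        )
    raise ValueError(f"unknown method {method!r} (expected one of {METHODS})")
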