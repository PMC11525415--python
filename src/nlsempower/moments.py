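"""Closed-form Gaussian moments of latent variables and their products.

For centered, jointly normal variables :math:`A, B, C, D` the Isserlis (Wick)
identities give

.. math::

    \\mathbb{E}[AB] = \\mathrm{Cov}(A,B), \\qquad
    \\mathrm{Cov}(AB, C) = 0,

.. math::

    \\mathrm{Cov}(AB, CD)
      = \\mathrm{Cov}(A,C)\\,\\mathrm{Cov}(B,D)
      + \\mathrm{Cov}(A,D)\\,\\mathrm{Cov}(B,C).

These identities make the covariance structure of a recursive structural
system with product terms available in closed form, as long as every latent
entering a product has a purely linear generating equation (so the product
factors are jointly normal).  Latents whose own equation contains product
terms are non-normal; they may appear linearly downstream, but not inside
further products — those moments are only available by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_syntax import ModelSpec, Term

__all__ = [
    "MomentTable",
    "MomentsError",
    "linear_latent_cov",
    "product_moments",
    "endogenous_variance",
    "residual_variance_for_unit_variance",
    "variance_increment",
    "scale_reliability",
]


class MomentsError(ValueError):
    """Analytic moments are unavailable for the requested quantity."""


Key = Term  # covariance table keys are Terms (linear terms have one variable)


def _as_term(x) -> Term:
    return x if isinstance(x, Term) else Term(x)


@dataclass
class MomentTable:
    """Symmetric table of covariances and means over latents and product terms."""

    covariance: dict[tuple[Term, Term], float] = field(default_factory=dict)
    means: dict[Term, float] = field(default_factory=dict)
    gaussian: set[Term] = field(default_factory=set)

    def set_cov(self, a, b, value: float) -> None:
        a, b = _as_term(a), _as_term(b)
        self.covariance[(a, b)] = value
        self.covariance[(b, a)] = value

    def cov(self, a, b) -> float:
        a, b = _as_term(a), _as_term(b)
        try:
            return self.covariance[(a, b)]
        except KeyError:
            raise MomentsError(f"no covariance entry for ({a}, {b})") from None

    def var(self, a) -> float:
        return self.cov(a, a)

    def mean(self, a) -> float:
        return self.means.get(_as_term(a), 0.0)

    def is_gaussian(self, name: str) -> bool:
        return Term(name) in self.gaussian


def linear_latent_cov(spec: ModelSpec) -> MomentTable:
    """Exact covariances among all latents of the recursive structural system.

    Exogenous latents carry their declared ``phi`` entries.  An endogenous
    latent defined by a purely linear equation in jointly normal inputs is
    itself normal; one whose equation contains product terms is non-normal but
    its variance and its covariances with normal latents are still exact
    (products of centered normals are uncorrelated with every linear term).
    """
    table = MomentTable()
    exo = spec.exogenous
    for a in exo:
        table.gaussian.add(Term(a))
        table.means[Term(a)] = spec.mean(a)
        for b in exo:
            table.set_cov(a, b, spec.variance(a, b))

    eq_products: dict[str, list[tuple[Term, float]]] = {}
    for lhs in spec.topological_order():
        if lhs in exo:
            continue
        terms = spec.equations[lhs]
        psi = spec.variance(lhs, lhs)
        linear = [(t, g) for t, g in terms if not t.is_product]
        products = [(t, g) for t, g in terms if t.is_product]
        for t, _ in products:
            for v in t.variables:
                if not table.is_gaussian(v):
                    raise MomentsError(
                        f"product term {t} in equation of {lhs!r} involves "
                        f"{v!r}, whose own equation contains product terms; "
                        f"analytic moments are unavailable (use simulation)"
                    )
        eq_products[lhs] = products
        # covariance with every variable already in the table
        known = [k.variables[0] for k in list(table.means) if len(k.variables) == 1]
        for other in known:
            c = sum(g * table.cov(t.variables[0], other) for t, g in linear)
            # products of centered normals are uncorrelated with every linear
            # (normal) term; with a non-normal latent they correlate through
            # that latent's own product terms
            if not table.is_gaussian(other):
                for t, g in products:
                    c += g * sum(
                        d * _product_cov(table, t, s)
                        for s, d in eq_products.get(other, [])
                    )
            table.set_cov(lhs, other, c)
        # own variance: gamma' Sigma gamma + psi over linear and product terms
        var = psi
        for ti, gi in linear:
            for tj, gj in linear:
                var += gi * gj * table.cov(ti.variables[0], tj.variables[0])
        for ti, gi in products:
            for tj, gj in products:
                var += gi * gj * _product_cov(table, ti, tj)
        table.set_cov(lhs, lhs, var)
        mean = spec.mean(lhs)
        mean += sum(g * _product_mean(table, t) for t, g in products)
        mean += sum(g * table.mean(t.variables[0]) for t, g in linear)
        table.means[Term(lhs)] = mean
        if not products and all(
            table.is_gaussian(t.variables[0]) for t, _ in linear
        ):
            table.gaussian.add(Term(lhs))
    return table


def _check_product_components(table: MomentTable, term: Term) -> None:
    for v in term.variables:
        if not table.is_gaussian(v):
            raise MomentsError(
                f"component {v!r} of product {term} is not normal; "
                f"analytic product moments unavailable"
            )


def _product_mean(table: MomentTable, term: Term) -> float:
    a, b = term.variables
    _check_product_components(table, term)
    return table.cov(a, b) + table.mean(a) * table.mean(b)


def _product_cov(table: MomentTable, s: Term, t: Term) -> float:
    a, b = s.variables
    c, d = t.variables
    _check_product_components(table, s)
    _check_product_components(table, t)
    return table.cov(a, c) * table.cov(b, d) + table.cov(a, d) * table.cov(b, c)


def product_moments(spec: ModelSpec, terms: list[Term]) -> MomentTable:
    """Extend :func:`linear_latent_cov` with moments of centered product terms.

    Product terms have mean ``Cov(A, B)`` (for zero-mean components), zero
    covariance with every linear term, and pairwise covariances given by the
    Isserlis identity.
    """
    table = linear_latent_cov(spec)
    linear_keys = [k for k in list(table.means)]
    for t in terms:
        if not t.is_product:
            continue
        table.means[t] = _product_mean(table, t)
        for other in linear_keys:
            table.set_cov(t, other, 0.0)
        for s in terms:
            if s.is_product and (s, t) not in table.covariance:
                table.set_cov(s, t, _product_cov(table, s, t))
        table.set_cov(t, t, _product_cov(table, t, t))
    return table


def _term_cov_matrix(spec: ModelSpec, latent: str):
    import numpy as np

    terms = spec.equations.get(latent)
    if terms is None:
        return [], np.zeros((0, 0))
    table = product_moments(spec, [t for t, _ in terms if t.is_product])
    tlist = [t for t, _ in terms]
    k = len(tlist)
    sigma = np.zeros((k, k))
    for i, ti in enumerate(tlist):
        for j, tj in enumerate(tlist):
            if ti.is_product and tj.is_product:
                sigma[i, j] = _product_cov(table, ti, tj)
            elif ti.is_product or tj.is_product:
                sigma[i, j] = 0.0
            else:
                sigma[i, j] = table.cov(ti.variables[0], tj.variables[0])
    return tlist, sigma


def endogenous_variance(spec: ModelSpec, latent: str) -> float:
    """Model-implied variance ``gamma' Sigma gamma + psi`` of an endogenous latent."""
    import numpy as np

    if latent not in spec.equations:
        return spec.variance(latent, latent)
    tlist, sigma = _term_cov_matrix(spec, latent)
    gamma = np.array([g for _, g in spec.equations[latent]])
    return float(gamma @ sigma @ gamma) + spec.variance(latent, latent)


def residual_variance_for_unit_variance(spec: ModelSpec, latent: str) -> float:
    """Residual variance that standardizes an endogenous latent to variance 1."""
    import numpy as np

    if latent not in spec.equations:
        return 1.0
    tlist, sigma = _term_cov_matrix(spec, latent)
    gamma = np.array([g for _, g in spec.equations[latent]])
    explained = float(gamma @ sigma @ gamma)
    if explained >= 1.0:
        raise MomentsError(
            f"explained variance of {latent!r} is {explained:.6g} >= 1; "
            f"no positive residual variance standardizes it"
        )
    return 1.0 - explained


def variance_increment(
    spec: ModelSpec,
    latent: str,
    term: Term,
    prior_terms: list[Term] | None = None,
) -> float:
    """Sequential explained-variance share contributed by one product term.

    The increment of `term`, given the product terms in `prior_terms` were
    already added, is

    ``[Var(g*term + sum prior) - Var(sum prior)] / Var(latent)``

    and therefore includes the covariances of `term` with previously added
    terms.  Individual increments depend on the ordering; their total over any
    ordering of the same term set does not.
    """
    import numpy as np

    prior_terms = list(prior_terms or [])
    tlist, sigma = _term_cov_matrix(spec, latent)
    coefs = dict(spec.equations[latent])
    if term not in coefs:
        raise MomentsError(f"term {term} not in equation of {latent!r}")
    for p in prior_terms:
        if p not in coefs:
            raise MomentsError(f"prior term {p} not in equation of {latent!r}")

    def block_var(active: list[Term]) -> float:
        g = np.array([coefs[t] if t in active else 0.0 for t in tlist])
        return float(g @ sigma @ g)

    total = endogenous_variance(spec, latent)
    with_term = block_var(prior_terms + [term])
    without = block_var(prior_terms)
    return (with_term - without) / total


def scale_reliability(spec: ModelSpec, latent: str) -> float:
    """Composite (sum-score) reliability of the scale measuring a latent.

    ``(sum lambda)^2 Var(latent) / ((sum lambda)^2 Var(latent) + sum theta)``.
    """
    inds = spec.measurement.get(latent, [])
    if not inds:
        return 1.0  # directly observed
    lam = sum(v for _, v in inds)
    theta = sum(spec.variance(name, name) for name, _ in inds)
    var = endogenous_variance(spec, latent)
    denom = lam**2 * var + theta
    if denom <= 0:
        raise MomentsError(f"zero total scale variance for {latent!r}")
    return lam**2 * var / denom
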