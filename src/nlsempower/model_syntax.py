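"""Parsing of population models written in a lavaan-dialect text syntax.

A population model is a plain-text description of a quadratic/interaction
structural equation model (QISEM) with *numeric population values* attached to
every parameter.  The supported operator subset is

======  =======================================  ===========================
``=~``  "is measured by"                          ``Xi1 =~ 1*x1 + 0.8*x2``
``~``   "is regressed on"                         ``Eta1 ~ 0.2*Xi1 + 0.1*Xi1:Xi2``
``~~``  "(co)variance"                            ``Xi1 ~~ 1*Xi1``
``:``   latent product (interaction/quadratic)    ``Xi1:Xi2``, ``Xi1:Xi1``
``~ c*1``  intercept / mean                       ``Eta1 ~ 0.5*1``
======  =======================================  ===========================

Every parameter must carry a numeric pre-multiplier (``value*name``): the model
is a *population*, not an estimation template, so free (unvalued) parameters are
rejected.  ``#`` starts a comment; whitespace is insignificant.

All (residual) variances must be stated explicitly: the variance of every
exogenous latent, the residual variance of every endogenous latent and the
error variance of every indicator.  Covariances default to zero, means and
intercepts default to zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "Term",
    "ParameterRef",
    "ModelSpec",
    "ModelSyntaxError",
    "parse_model",
    "serialize_model",
    "count_parameters",
]

_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_NAME_RE = re.compile(rf"^{_NAME}$")


class ModelSyntaxError(ValueError):
    """Raised for any malformed or inconsistent model text."""


@dataclass(frozen=True, order=True)
class Term:
    """A right-hand-side term of a structural equation.

    One variable -> linear term; two -> product term (identical pair means a
    quadratic term).  Products are order-insensitive: ``Xi1:Xi2 == Xi2:Xi1``.
    """

    variables: tuple[str, ...]

    def __init__(self, *variables: str):
        if len(variables) not in (1, 2):
            raise ModelSyntaxError(
                f"a term must involve 1 or 2 variables, got {variables!r}"
            )
        object.__setattr__(self, "variables", tuple(sorted(variables)))

    @property
    def is_product(self) -> bool:
        return len(self.variables) == 2

    @property
    def is_quadratic(self) -> bool:
        return self.is_product and self.variables[0] == self.variables[1]

    def __str__(self) -> str:
        return ":".join(self.variables)


@dataclass(frozen=True)
class ParameterRef:
    """Address of a structural coefficient (a parameter of interest).

    ``ParameterRef.parse("Eta1 ~ Xi1:Xi2")`` resolves to the coefficient of the
    ``Xi1:Xi2`` product in the equation of ``Eta1``.
    """

    lhs: str
    term: Term

    @classmethod
    def parse(cls, text: str) -> "ParameterRef":
        compact = text.replace(" ", "").replace("\t", "")
        if compact.count("~") != 1 or "~~" in compact:
            raise ModelSyntaxError(f"cannot parse parameter reference {text!r}")
        lhs, rhs = compact.split("~")
        names = rhs.split(":")
        if not lhs or not all(names):
            raise ModelSyntaxError(f"cannot parse parameter reference {text!r}")
        return cls(lhs, Term(*names))

    def __str__(self) -> str:
        return f"{self.lhs}~{self.term}"


@dataclass
class ModelSpec:
    """A validated population QISEM.

    Attributes
    ----------
    latents:
        All latent names in declaration order.  Variables used in structural
        statements without a measurement block are treated as latents observed
        directly (single perfect indicator), which also covers manifest path
        models.
    measurement:
        latent -> list of ``(indicator, loading)`` pairs.
    equations:
        endogenous latent -> list of ``(Term, coefficient)``.
    variances:
        ``(a, b)`` (sorted pair) -> value.  Diagonal entries are variances of
        exogenous latents, residual variances of endogenous latents or
        measurement-error variances of indicators.
    means:
        variable -> mean/intercept (defaults to 0 when absent).
    """

    latents: list[str] = field(default_factory=list)
    measurement: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    equations: dict[str, list[tuple[Term, float]]] = field(default_factory=dict)
    variances: dict[tuple[str, str], float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)

    # -- convenience views ---------------------------------------------------
    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.latents if v in self.equations]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.latents if v not in self.equations]

    @property
    def indicators(self) -> list[str]:
        cols: list[str] = []
        for lat in self.latents:
            inds = self.measurement.get(lat, [])
            if inds:
                cols.extend(name for name, _ in inds)
            else:
                cols.append(lat)  # directly observed
        return cols

    def indicator_names(self, latent: str) -> list[str]:
        inds = self.measurement.get(latent, [])
        return [name for name, _ in inds] if inds else [latent]

    def variance(self, a: str, b: str | None = None) -> float:
        b = a if b is None else b
        return self.variances.get(tuple(sorted((a, b))), 0.0)

    def mean(self, name: str) -> float:
        return self.means.get(name, 0.0)

    def coefficient(self, ref: ParameterRef) -> float:
        for term, value in self.equations.get(ref.lhs, []):
            if term == ref.term:
                return value
        raise KeyError(f"no coefficient {ref} in model")

    def product_terms(self) -> list[Term]:
        seen: list[Term] = []
        for terms in self.equations.values():
            for term, _ in terms:
                if term.is_product and term not in seen:
                    seen.append(term)
        return seen

    def topological_order(self) -> list[str]:
        """Latents ordered so every equation only uses earlier variables."""
        order: list[str] = [v for v in self.latents if v not in self.equations]
        remaining = dict(self.equations)
        while remaining:
            progressed = False
            for lhs in list(remaining):
                deps = {v for term, _ in remaining[lhs] for v in term.variables}
                if deps <= set(order):
                    order.append(lhs)
                    del remaining[lhs]
                    progressed = True
            if not progressed:
                raise ModelSyntaxError(
                    "cyclic structural system involving: "
                    + ", ".join(sorted(remaining))
                )
        return order

    def validate(self) -> None:
        indicator_owner: dict[str, str] = {}
        for lat, inds in self.measurement.items():
            for name, _ in inds:
                if name in indicator_owner:
                    raise ModelSyntaxError(
                        f"indicator {name!r} appears under both "
                        f"{indicator_owner[name]!r} and {lat!r}"
                    )
                if name in self.latents:
                    raise ModelSyntaxError(
                        f"{name!r} is both a latent and an indicator"
                    )
                indicator_owner[name] = lat
        for lhs, terms in self.equations.items():
            for term, _ in terms:
                for v in term.variables:
                    if v not in self.latents:
                        raise ModelSyntaxError(
                            f"undeclared variable {v!r} in equation of {lhs!r}"
                        )
        self.topological_order()  # raises on cycles
        # mandatory variances
        missing = [v for v in self.latents if (v, v) not in self.variances]
        missing += [
            name
            for lat, inds in self.measurement.items()
            for name, _ in inds
            if (name, name) not in self.variances
        ]
        if missing:
            raise ModelSyntaxError(
                "missing (residual) variance for: " + ", ".join(missing)
            )
        def block(name: str) -> str:
            if name in self.equations:
                return "residual"
            if name in self.latents:
                return "exogenous"
            return "error"

        for (a, b), val in self.variances.items():
            if a != b and block(a) != block(b):
                raise ModelSyntaxError(
                    f"covariance between {a!r} ({block(a)}) and {b!r} "
                    f"({block(b)}) is not supported"
                )
            if a == b and val < 0:
                raise ModelSyntaxError(f"negative variance for {a!r}: {val}")
            if a == b and val == 0 and a in self.exogenous:
                raise ModelSyntaxError(f"zero variance for exogenous {a!r}")
        # exogenous covariance matrix must be positive definite
        exo = self.exogenous
        if exo:
            import numpy as np

            phi = np.array(
                [[self.variance(a, b) for b in exo] for a in exo], dtype=float
            )
            if np.linalg.eigvalsh(phi).min() <= 0:
                raise ModelSyntaxError(
                    "covariance matrix of exogenous latents is not positive "
                    "definite"
                )


def _parse_premultiplied(chunk: str, statement: str) -> tuple[float, str]:
    """Split ``value*expr``; population values are mandatory."""
    if "*" not in chunk:
        raise ModelSyntaxError(
            f"missing numeric population value in {statement!r} "
            f"(every parameter must be written as value*name)"
        )
    pre, _, expr = chunk.partition("*")
    try:
        value = float(pre)
    except ValueError:
        raise ModelSyntaxError(
            f"non-numeric pre-multiplier {pre!r} in {statement!r} "
            f"(labels/constraints are not supported)"
        ) from None
    if not math.isfinite(value):
        raise ModelSyntaxError(f"non-finite value in {statement!r}")
    return value, expr


def parse_model(text: str) -> ModelSpec:
    """Parse lavaan-dialect model text into a validated :class:`ModelSpec`."""
    spec = ModelSpec()
    declared: list[str] = []  # latent declaration order

    def declare(name: str) -> None:
        if name not in declared:
            declared.append(name)

    statements: list[tuple[str, str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].replace(" ", "").replace("\t", "")
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            idx = line.find(op)
            # make sure "~" does not greedily match the first char of "~~"/"=~"
            if op == "~":
                m = re.search(r"(?<![=~])~(?!~)", line)
                idx = m.start() if m else -1
            if idx > 0:
                lhs, rhs = line[:idx], line[idx + len(op):]
                statements.append((op, lhs, rhs))
                break
        else:
            raise ModelSyntaxError(f"cannot parse statement {raw.strip()!r}")

    # first pass: declare latents (measurement + structural lhs/rhs)
    for op, lhs, rhs in statements:
        if not _NAME_RE.match(lhs):
            raise ModelSyntaxError(f"invalid name {lhs!r}")
        if op == "=~":
            declare(lhs)
        elif op == "~":
            declare(lhs)

    indicator_set: set[str] = set()
    for op, lhs, rhs in statements:
        if op != "=~":
            continue
        loadings = []
        for chunk in rhs.split("+"):
            value, name = _parse_premultiplied(chunk, f"{lhs} =~ {rhs}")
            if not _NAME_RE.match(name):
                raise ModelSyntaxError(f"invalid indicator name {name!r}")
            loadings.append((name, value))
            indicator_set.add(name)
        spec.measurement.setdefault(lhs, []).extend(loadings)

    for op, lhs, rhs in statements:
        if op != "~":
            continue
        for chunk in rhs.split("+"):
            value, expr = _parse_premultiplied(chunk, f"{lhs} ~ {rhs}")
            if expr == "1":
                spec.means[lhs] = spec.means.get(lhs, 0.0) + value
                continue
            names = expr.split(":")
            for name in names:
                if not _NAME_RE.match(name):
                    raise ModelSyntaxError(f"invalid name {name!r}")
                if name in indicator_set:
                    raise ModelSyntaxError(
                        f"{name!r} is an indicator; structural terms must "
                        f"reference latents"
                    )
                declare(name)
            spec.equations.setdefault(lhs, []).append((Term(*names), value))

    for op, lhs, rhs in statements:
        if op != "~~":
            continue
        chunks = rhs.split("+")
        for chunk in chunks:
            value, name = _parse_premultiplied(chunk, f"{lhs} ~~ {rhs}")
            if not _NAME_RE.match(name):
                raise ModelSyntaxError(f"invalid name {name!r}")
            # a name seen only in (co)variance statements is a directly
            # observed exogenous variable
            for v in (lhs, name):
                if v not in indicator_set:
                    declare(v)
            key = tuple(sorted((lhs, name)))
            spec.variances[key] = spec.variances.get(key, 0.0) + value

    spec.latents = declared
    spec.validate()
    return spec


def serialize_model(spec: ModelSpec) -> str:
    """Canonical text for a ModelSpec; ``parse_model(serialize_model(s)) == s``."""
    lines: list[str] = []
    for lat in spec.latents:
        inds = spec.measurement.get(lat, [])
        if inds:
            lines.append(f"{lat} =~ " + " + ".join(f"{v}*{n}" for n, v in inds))
    for lhs, terms in spec.equations.items():
        lines.append(
            f"{lhs} ~ " + " + ".join(f"{v}*{t}" for t, v in terms)
        )
    for lhs, mean in spec.means.items():
        if mean != 0.0:
            lines.append(f"{lhs} ~ {mean}*1")
    for (a, b), v in spec.variances.items():
        lines.append(f"{a} ~~ {v}*{b}")
    return "\n".join(lines) + "\n"


def count_parameters(spec: ModelSpec, method: str) -> int:
    """Number of free parameters of the model actually fitted by `method`.

    Used for the default sample-size bounds ``n_lb = 5 * #par`` and
    ``n_start = 10 * #par``.

    SR and FSR fit a recursive path model on (scale or factor) scores: each
    equation contributes its slopes, an intercept and a residual variance.

    UPI fits the augmented linear SEM: free loadings (one marker per latent
    fixed to 1), all measurement-error variances, structural slopes, residual
    variances of endogenous latents and the full free covariance block among
    exogenous latents and latent product factors.
    """
    method = method.upper()
    if method in ("SR", "FSR"):
        return sum(len(terms) + 2 for terms in spec.equations.values())
    if method == "UPI":
        from .estimators import matched_product_indicator_count

        n_lat = len(spec.latents)
        n_ind = sum(
            len(spec.measurement.get(lat, [])) or 1 for lat in spec.latents
        )
        products = spec.product_terms()
        n_lat += len(products)
        n_ind += sum(matched_product_indicator_count(spec, t) for t in products)
        free_loadings = n_ind - n_lat  # one marker loading fixed per latent
        error_vars = n_ind
        structural = sum(len(terms) for terms in spec.equations.values())
        resid = len(spec.endogenous)
        k = len(spec.exogenous) + len(products)
        exo_block = k * (k + 1) // 2
        return free_loadings + error_vars + structural + resid + exo_block
    if method == "LMS":
        raise NotImplementedError(
            "LMS requires external Mplus and is out of scope"
        )
    raise ValueError(f"unknown method {method!r} (expected SR, FSR or UPI)")
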