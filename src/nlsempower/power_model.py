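"""Power-curve modeling: significance decisions, probit/logit fit in sqrt(n),
and inversion for required sample sizes.

The probability that the z-test of a parameter of interest (POI) is
significant in a sample of size :math:`n` is modeled as

.. math::

    P(S = 1 \\mid n) = \\Phi(\\beta_0 + \\beta_1 \\sqrt{n})

(or its logistic analogue).  Asymptotically :math:`\\beta_0 = -q_{1-\\alpha}`
and :math:`\\beta_1 = |\\vartheta_0| / \\omega` with :math:`\\omega` the
asymptotic standard deviation of the estimator, which is what makes the square
root of the sample size the natural predictor.  The fitted curve is inverted
for the required sample size

.. math::

    N_\\alpha = \\lceil ((\\Phi^{-1}(\\rho) - \\beta_0)/\\beta_1)^2 \\rceil,

and — acknowledging that the curve itself is estimated — for the conservative
:math:`N_{\\alpha,\\mathrm{lb}}`: the smallest *n* whose *lower* confidence
band reaches the target power, which is at least :math:`N_\\alpha` with
probability about :math:`1 - \\alpha_\\rho/2`.

The binary regression is a two-parameter GLM fitted here by Fisher scoring on
binomially aggregated data (records share few distinct sample sizes, so
aggregation makes the fit essentially free); the coefficient covariance is the
inverse observed information.  The implementation is cross-checked against
statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .estimators import FitResult
from .model_syntax import ModelSpec, ParameterRef

__all__ = [
    "SignificanceRecord",
    "PowerModelFit",
    "SeparationError",
    "significance_decisions",
    "fit_power_model",
    "predict_power",
    "required_n",
    "required_n_lb",
    "band_crossing_n",
]

N_CEILING = 10**7


class SeparationError(RuntimeError):
    """The power regression cannot be fitted (all decisions identical)."""


@dataclass
class SignificanceRecord:
    """Significance decisions of one replication at sample size ``n``."""

    n: int
    converged: bool
    decisions: dict[str, int] = field(default_factory=dict)


@dataclass
class PowerModelFit:
    """Fitted power curve on the sqrt(n) scale."""

    link: str
    beta0: float
    beta1: float
    vcov: np.ndarray  # 2x2 coefficient covariance
    n_records: int

    @property
    def coefficients(self) -> tuple[float, float]:
        return self.beta0, self.beta1


def _links(link: str):
    if link == "probit":
        return norm.cdf, norm.ppf, norm.pdf
    if link == "logit":
        cdf = lambda x: 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))

        def ppf(p):
            p = np.asarray(p, dtype=float)
            return np.log(p / (1.0 - p))

        pdf = lambda x: cdf(x) * (1.0 - cdf(x))
        return cdf, ppf, pdf
    raise ValueError(f"unknown power model link {link!r} (probit or logit)")


def significance_decisions(
    fits: list[FitResult],
    pois: list[ParameterRef],
    alpha: float,
    test: str,
    spec: ModelSpec,
) -> list[SignificanceRecord]:
    """Turn per-replication fits into 0/1 significance decisions per POI.

    One-sided tests are directional in the sign of the population
    coefficient: ``S = 1`` iff ``sign(gamma_0) * z > q(1 - alpha)``.
    Two-sided: ``S = 1`` iff ``|z| > q(1 - alpha/2)``.  Nonconverged fits
    carry no decisions.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if test not in ("onesided", "twosided"):
        raise ValueError(f"unknown test {test!r} (onesided or twosided)")
    q = norm.ppf(1 - alpha) if test == "onesided" else norm.ppf(1 - alpha / 2)
    directions = {str(p): np.sign(spec.coefficient(p)) or 1.0 for p in pois}
    records = []
    for fit in fits:
        if not fit.converged:
            records.append(SignificanceRecord(fit.n, False))
            continue
        decisions = {}
        for poi in pois:
            est, se = fit.resolve(poi)
            z = est / se
            if test == "onesided":
                decisions[str(poi)] = int(directions[str(poi)] * z > q)
            else:
                decisions[str(poi)] = int(abs(z) > q)
        records.append(SignificanceRecord(fit.n, True, decisions))
    return records


def _aggregate(records: list[SignificanceRecord], poi_key: str):
    ns, ss = [], []
    for r in records:
        if r.converged and poi_key in r.decisions:
            ns.append(r.n)
            ss.append(r.decisions[poi_key])
    if not ns:
        raise SeparationError("no converged records to fit the power model")
    ns = np.asarray(ns, dtype=float)
    ss = np.asarray(ss, dtype=float)
    uniq, inv = np.unique(ns, return_inverse=True)
    trials = np.bincount(inv).astype(float)
    successes = np.bincount(inv, weights=ss)
    return np.sqrt(uniq), trials, successes, len(ns)


def fit_power_model(
    records: list[SignificanceRecord],
    poi,
    link: str = "probit",
) -> PowerModelFit:
    """ML fit of the binary regression of decisions on sqrt(n).

    Raises :class:`SeparationError` when all decisions are identical (the
    remedy is to widen the range of simulated sample sizes).
    """
    poi_key = str(poi)
    cdf, ppf, pdf = _links(link)
    x, m, s, n_rec = _aggregate(records, poi_key)
    if s.sum() == 0 or s.sum() == m.sum():
        raise SeparationError(
            "complete separation: all significance decisions are "
            f"{'1' if s.sum() else '0'}; widen the range of sample sizes"
        )
    if len(x) < 2:
        raise SeparationError(
            "need records at >= 2 distinct sample sizes to fit the power curve"
        )
    # start: weighted LS on the link-transformed empirical rates
    rate = np.clip(s / m, 1.0 / (m + 2), (m + 1) / (m + 2))
    zt = ppf(rate)
    w = m
    xw = np.column_stack([np.ones_like(x), x])
    wls = np.linalg.lstsq(xw * np.sqrt(w)[:, None], zt * np.sqrt(w), rcond=None)
    beta = wls[0]

    def loglik_parts(beta):
        eta = beta[0] + beta[1] * x
        p = np.clip(cdf(eta), 1e-12, 1 - 1e-12)
        ll = float(s @ np.log(p) + (m - s) @ np.log1p(-p))
        if link == "logit":
            g_eta = s - m * p
            h_eta = -m * p * (1 - p)
        else:
            phi = pdf(eta)
            g_eta = phi * (s / p - (m - s) / (1 - p))
            h_eta = -eta * g_eta - phi**2 * (s / p**2 + (m - s) / (1 - p) ** 2)
        grad = xw.T @ g_eta
        hess = xw.T @ (h_eta[:, None] * xw)
        return ll, grad, hess

    ll, grad, hess = loglik_parts(beta)
    for _ in range(100):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix in the power-model fit; widen "
                "the range of sample sizes"
            ) from None
        # step-halving line search on the log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, grad_new, hess_new = loglik_parts(cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(grad).max() < 1e-8:
            break
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e4:
        raise SeparationError(
            "power-model coefficients diverged (quasi-separation); widen "
            "the range of sample sizes"
        )
    try:
        vcov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        raise SeparationError("singular observed information") from None
    return PowerModelFit(link, float(beta[0]), float(beta[1]), vcov, n_rec)


def predict_power(fit: PowerModelFit, n, alpha_rho: float = 0.05):
    """Point prediction and confidence band of the power at sample size ``n``.

    The band is computed on the linear-predictor scale and transformed
    through the link, so its endpoints stay inside (0, 1).
    """
    cdf, _, _ = _links(fit.link)
    n_arr = np.asarray(n, dtype=float)
    root = np.sqrt(n_arr)
    lp = fit.beta0 + fit.beta1 * root
    v = np.stack([np.ones_like(root), root])
    var_lp = np.einsum("i...,ij,j...->...", v, fit.vcov, v)
    half = norm.ppf(1 - alpha_rho / 2) * np.sqrt(np.clip(var_lp, 0.0, None))
    point, lower, upper = cdf(lp), cdf(lp - half), cdf(lp + half)
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(point), float(lower), float(upper)
    return point, lower, upper


def required_n(fit_or_coefficients, rho: float, link: str = "probit") -> int:
    """Required sample size: inversion of the fitted power curve at ``rho``."""
    if isinstance(fit_or_coefficients, PowerModelFit):
        beta0, beta1 = fit_or_coefficients.coefficients
        link = fit_or_coefficients.link
    else:
        beta0, beta1 = fit_or_coefficients
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if beta1 <= 0:
        raise ValueError(
            "power curve has non-positive slope; no finite sample size "
            "reaches the target power"
        )
    _, ppf, _ = _links(link)
    root = (float(ppf(rho)) - beta0) / beta1
    if root <= 1.0:
        return 1
    # tolerance keeps exact inversions (rho = power at integer n) exact
    return int(np.ceil(root**2 - 1e-9))


def band_crossing_n(
    fit: PowerModelFit, rho: float, alpha_rho: float, band: str,
    integer: bool = True,
):
    """Smallest n at which the chosen confidence band reaches ``rho``.

    ``band="lower"`` gives the conservative bound (>= N_alpha);
    ``band="upper"`` the liberal one (<= N_alpha).  Found by doubling plus
    bisection, relying on the monotone increase of the band along n
    (beta1 > 0).  With ``integer=False`` the continuous crossing point is
    returned instead of its ceiling — the quantity whose sampling
    distribution carries the nominal confidence level, free of the
    integer-rounding granularity.
    """
    idx = {"lower": 1, "upper": 2}[band]
    if fit.beta1 <= 0:
        raise ValueError("power curve has non-positive slope")

    def reached(n) -> bool:
        return predict_power(fit, n, alpha_rho)[idx] >= rho

    n_alpha = required_n(fit, rho)
    if band == "upper":
        lo, hi = 1, n_alpha
        if reached(lo):
            return 1 if integer else 1.0
    else:
        lo, hi = n_alpha, n_alpha
        if reached(lo) and integer:
            return lo
        while not reached(hi):
            lo, hi = hi, hi * 2
            if hi > N_CEILING:
                raise RuntimeError(
                    f"the {band} confidence band never reaches {rho} below "
                    f"n = {N_CEILING}; increase the number of replications"
                )
    if integer:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if reached(mid):
                hi = mid
            else:
                lo = mid
        return hi
    from scipy.optimize import brentq

    f = lambda n: predict_power(fit, n, alpha_rho)[idx] - rho
    _, ppf, _ = _links(fit.link)
    n_point = max(((float(ppf(rho)) - fit.beta0) / fit.beta1) ** 2, 1.0)
    if band == "lower":
        lo = n_point  # the band crossing sits at or above the point crossing
    else:
        hi = n_point
        lo = 1.0
    if f(lo) >= 0:
        return float(lo)
    return float(brentq(f, float(lo), float(hi), xtol=1e-6))


def required_n_lb(fit: PowerModelFit, rho: float, alpha_rho: float = 0.05) -> int:
    """Conservative required sample size from the lower confidence band.

    Always >= :func:`required_n`; equals it when the coefficient covariance
    is zero.
    """
    return band_crossing_n(fit, rho, alpha_rho, "lower")
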