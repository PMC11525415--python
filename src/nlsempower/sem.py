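"""Maximum-likelihood fitting of linear covariance-structure models.

The model is the all-latent (LISREL all-y) form

.. math::

    x = \\Lambda \\eta + \\varepsilon, \\qquad
    \\eta = B \\eta + \\zeta,

with implied covariance
:math:`\\Sigma(\\theta) = \\Lambda (I-B)^{-1} \\Psi (I-B)^{-\\top} \\Lambda^\\top + \\Theta`.
The mean structure is dropped (data are centered before fitting), which is the
natural companion of double-mean-centered product indicators.

The discrepancy minimized is the normal-theory ML fit function

.. math::

    F(\\theta) = \\log|\\Sigma(\\theta)| + \\mathrm{tr}(S\\Sigma(\\theta)^{-1})
                 - \\log|S| - p,

by quasi-Newton iteration with an analytic gradient (every free parameter
perturbs :math:`\\Sigma` by a rank-two update, so the gradient is cheap and
exact).  Standard errors are the sandwich :math:`(H^{-1} I H^{-1})/n` with
``H`` the numerical Hessian of the average casewise objective and ``I`` the
empirical covariance of the casewise scores — robust to non-normality of the
observations, which product indicators always exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["SemTemplate", "SemFit", "fit_linear_sem"]

_MAXITER = 500
_GTOL = 1e-8


@dataclass
class SemTemplate:
    """Free-parameter layout of a linear covariance-structure model.

    ``loadings`` maps ``(indicator, latent)`` to a fixed float or the string
    ``"free"``; ``structural`` lists free ``(lhs, rhs)`` paths; ``psi`` maps
    sorted latent pairs to fixed values or ``"free"`` (diagonal entries are
    latent/residual variances); ``theta`` likewise for indicator error
    (co)variances.  Anything absent is fixed at zero.
    """

    obs_names: list[str]
    latent_names: list[str]
    loadings: dict[tuple[str, str], float | str] = field(default_factory=dict)
    structural: list[tuple[str, str]] = field(default_factory=list)
    psi: dict[tuple[str, str], float | str] = field(default_factory=dict)
    theta: dict[tuple[str, str], float | str] = field(default_factory=dict)

    def n_free(self) -> int:
        free = sum(1 for v in self.loadings.values() if v == "free")
        free += len(self.structural)
        free += sum(1 for v in self.psi.values() if v == "free")
        free += sum(1 for v in self.theta.values() if v == "free")
        return free

    def check_identified(self) -> None:
        p = len(self.obs_names)
        if self.n_free() > p * (p + 1) // 2:
            raise ValueError(
                f"template has {self.n_free()} free parameters but only "
                f"{p * (p + 1) // 2} observed moments"
            )

    @classmethod
    def saturated(cls, obs_names: list[str]) -> "SemTemplate":
        """All observed (co)variances free: fits S exactly with F = 0."""
        theta: dict[tuple[str, str], float | str] = {}
        for i, a in enumerate(obs_names):
            for b in obs_names[i:]:
                theta[tuple(sorted((a, b)))] = "free"
        return cls(obs_names=list(obs_names), latent_names=[], theta=theta)


@dataclass
class SemFit:
    """Converged (or not) solution of :func:`fit_linear_sem`."""

    template: SemTemplate
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    n: int
    fmin: float
    message: str = ""


class _Parametrization:
    """Maps a flat parameter vector onto (Lambda, B, Psi, Theta)."""

    def __init__(self, template: SemTemplate, start: np.ndarray | None = None):
        self.t = template
        self.obs_index = {n: i for i, n in enumerate(template.obs_names)}
        self.lat_index = {n: i for i, n in enumerate(template.latent_names)}
        self.p = len(template.obs_names)
        self.m = len(template.latent_names)
        # fixed parts
        self.lam0 = np.zeros((self.p, self.m))
        self.b0 = np.zeros((self.m, self.m))
        self.psi0 = np.zeros((self.m, self.m))
        self.th0 = np.zeros((self.p, self.p))
        self.free: list[tuple[str, int, int]] = []
        for (ind, lat), v in template.loadings.items():
            i, j = self.obs_index[ind], self.lat_index[lat]
            if v == "free":
                self.free.append(("lam", i, j))
            else:
                self.lam0[i, j] = float(v)
        for lhs, rhs in template.structural:
            self.free.append(("b", self.lat_index[lhs], self.lat_index[rhs]))
        for (a, b), v in template.psi.items():
            i, j = self.lat_index[a], self.lat_index[b]
            if v == "free":
                self.free.append(("psi", i, j))
            else:
                self.psi0[i, j] = self.psi0[j, i] = float(v)
        for (a, b), v in template.theta.items():
            i, j = self.obs_index[a], self.obs_index[b]
            if v == "free":
                self.free.append(("th", i, j))
            else:
                self.th0[i, j] = self.th0[j, i] = float(v)
        self.k = len(self.free)

    def start_values(self, sample_var: np.ndarray) -> np.ndarray:
        """Loadings 1, error variances half the indicator variance, latent
        variances half the marker variance, everything else 0."""
        theta = np.zeros(self.k)
        # marker indicator per latent: first fixed loading's indicator, else 0
        marker_var = np.full(self.m, 1.0)
        for (ind, lat), v in self.t.loadings.items():
            if v != "free" and float(v) != 0.0:
                marker_var[self.lat_index[lat]] = sample_var[self.obs_index[ind]]
        for idx, (kind, i, j) in enumerate(self.free):
            if kind == "lam":
                theta[idx] = 1.0
            elif kind == "th":
                theta[idx] = 0.5 * sample_var[i] if i == j else 0.0
            elif kind == "psi":
                theta[idx] = 0.5 * marker_var[i] if i == j else 0.0
            else:  # structural path
                theta[idx] = 0.0
        return theta

    def matrices(self, theta: np.ndarray):
        lam = self.lam0.copy()
        b = self.b0.copy()
        psi = self.psi0.copy()
        th = self.th0.copy()
        for val, (kind, i, j) in zip(theta, self.free):
            if kind == "lam":
                lam[i, j] = val
            elif kind == "b":
                b[i, j] = val
            elif kind == "psi":
                psi[i, j] = psi[j, i] = val
            else:
                th[i, j] = th[j, i] = val
        return lam, b, psi, th

    def implied(self, theta: np.ndarray):
        lam, b, psi, th = self.matrices(theta)
        if self.m:
            m_inv = np.linalg.inv(np.eye(self.m) - b)
            a = m_inv @ psi @ m_inv.T
            g = lam @ m_inv  # p x m
            sigma = lam @ a @ lam.T + th
        else:
            m_inv = np.zeros((0, 0))
            a = m_inv
            g = np.zeros((self.p, 0))
            sigma = th.copy()
        return sigma, lam, m_inv, a, g

    def d_sigma_vectors(self, theta: np.ndarray):
        """Each free parameter's dSigma as a rank-2 update outer(a,b)+outer(b,a)
        (or outer(a,a) for diagonal entries): returns list of (a, b) with b=None
        meaning the one-sided (diagonal) case."""
        sigma, lam, m_inv, a_mat, g = self.implied(theta)
        k_mat = lam @ m_inv if self.m else np.zeros((self.p, 0))
        ga = lam @ a_mat if self.m else np.zeros((self.p, 0))
        eye = np.eye(self.p)
        out = []
        for kind, i, j in self.free:
            if kind == "lam":
                out.append((eye[:, i], ga[:, j]))
            elif kind == "b":
                out.append((k_mat[:, i], ga[:, j]))
            elif kind == "psi":
                if i == j:
                    out.append((k_mat[:, i], None))
                else:
                    out.append((k_mat[:, i], k_mat[:, j]))
            else:
                if i == j:
                    out.append((eye[:, i], None))
                else:
                    out.append((eye[:, i], eye[:, j]))
        return sigma, out


def _objective_and_grad(param: _Parametrization, theta: np.ndarray, s: np.ndarray):
    sigma, dvecs = param.d_sigma_vectors(theta)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # non-PD candidate: large finite value keeps the line search sane
        return 1e12, np.zeros(param.k)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + float(np.trace(s @ sigma_inv))
    w = sigma_inv - sigma_inv @ s @ sigma_inv  # dF/dSigma
    grad = np.empty(param.k)
    for idx, (a, b) in enumerate(dvecs):
        if b is None:
            grad[idx] = float(a @ w @ a)
        else:
            grad[idx] = 2.0 * float(a @ w @ b)
    return f, grad


def _casewise_scores(param: _Parametrization, theta: np.ndarray, z: np.ndarray):
    """Scores of f_i = (log|Sigma| + z_i' Sigma^-1 z_i)/2 for each observation."""
    sigma, dvecs = param.d_sigma_vectors(theta)
    sigma_inv = np.linalg.inv(sigma)
    u = z @ sigma_inv  # n x p
    n = z.shape[0]
    scores = np.empty((n, param.k))
    for idx, (a, b) in enumerate(dvecs):
        if b is None:
            tr = float(a @ sigma_inv @ a)
            scores[:, idx] = 0.5 * (tr - (u @ a) ** 2)
        else:
            tr = 2.0 * float(a @ sigma_inv @ b)
            scores[:, idx] = 0.5 * (tr - 2.0 * (u @ a) * (u @ b))
    return scores


def _numeric_hessian(fun_grad, theta: np.ndarray, eps: float = 1e-5):
    k = theta.size
    h = np.empty((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += step
        tm[i] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        h[i] = (gp - gm) / (2 * step)
    return 0.5 * (h + h.T)


def fit_linear_sem(
    data,
    template: SemTemplate,
    robust: bool = True,
) -> SemFit:
    """Fit a linear SEM to raw data (``n x p`` array or DataFrame) by ML.

    Returns parameter estimates keyed by lavaan-style addresses
    (``"lat=~ind"``, ``"lhs~rhs"``, ``"a~~b"``), sandwich (or information)
    standard errors, and a convergence flag.  Nonconvergence, a non-invertible
    Hessian or an improper solution (negative variance estimate) is flagged,
    never raised.
    """
    template.check_identified()
    x = np.asarray(getattr(data, "values", data), dtype=float)
    cols = list(getattr(data, "columns", template.obs_names))
    order = [cols.index(name) for name in template.obs_names]
    x = x[:, order]
    n, p = x.shape
    z = x - x.mean(axis=0)
    s = z.T @ z / n
    param = _Parametrization(template)

    def labels() -> list[str]:
        lab = []
        for kind, i, j in param.free:
            if kind == "lam":
                lab.append(f"{template.latent_names[j]}=~{template.obs_names[i]}")
            elif kind == "b":
                lab.append(f"{template.latent_names[i]}~{template.latent_names[j]}")
            elif kind == "psi":
                a, b = template.latent_names[i], template.latent_names[j]
                lab.append(f"{min(a,b)}~~{max(a,b)}")
            else:
                a, b = template.obs_names[i], template.obs_names[j]
                lab.append(f"{min(a,b)}~~{max(a,b)}")
        return lab

    def failed(msg: str) -> SemFit:
        return SemFit(template, {}, {}, False, n, np.nan, msg)

    if n <= param.k or np.linalg.matrix_rank(s) < p:
        return failed("sample too small or singular sample covariance")
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        return failed("sample covariance not positive definite")

    theta0 = param.start_values(np.diag(s))

    def fun_grad(t):
        return _objective_and_grad(param, t, s)

    res = minimize(
        fun_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": _MAXITER, "gtol": _GTOL, "ftol": 1e-12},
    )
    theta = res.x
    f_val, grad = fun_grad(theta)
    if not np.isfinite(f_val) or np.linalg.norm(grad, np.inf) > 1e-4:
        # one polish attempt from the L-BFGS solution
        res = minimize(
            fun_grad, theta, jac=True, method="BFGS",
            options={"maxiter": _MAXITER, "gtol": _GTOL},
        )
        theta = res.x
        f_val, grad = fun_grad(theta)
    fmin = f_val - logdet_s - p
    if not np.isfinite(f_val) or np.linalg.norm(grad, np.inf) > 1e-3:
        return failed("optimizer did not reach a stationary point")

    lam, b, psi, th = param.matrices(theta)
    if (psi.size and np.diag(psi).min() < -1e-8) or (
        th.size and np.diag(th).min() < -1e-8
    ):
        return failed("improper solution (negative variance estimate)")

    # sandwich covariance: H^-1 I H^-1 / n on the average casewise objective
    def half_fun_grad(t):
        f, g = _objective_and_grad(param, t, s)
        return 0.5 * f, 0.5 * g

    h = _numeric_hessian(half_fun_grad, theta)
    try:
        h_inv = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return failed("non-invertible Hessian at the solution")
    if robust:
        scores = _casewise_scores(param, theta, z)
        i_mat = scores.T @ scores / n
        acov = h_inv @ i_mat @ h_inv / n
    else:
        acov = h_inv / n
    se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    if not np.all(np.isfinite(se)) or np.any(se == 0):
        return failed("degenerate standard errors")

    lab = labels()
    return SemFit(
        template=template,
        estimates=dict(zip(lab, theta.tolist())),
        standard_errors=dict(zip(lab, se.tolist())),
        converged=True,
        n=n,
        fmin=float(fmin),
        message=res.message if isinstance(res.message, str) else "",
    )
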