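"""Quantile regression for unit-interval responses.

The UBXII quantile regression links the ``tau``-th quantile ``q_i`` of
each response to a linear predictor, ``g(q_i) = x_i' beta``, with a single
shape parameter ``c`` common to all observations.  Fitting is by maximum
likelihood: BFGS on ``(beta, log c)`` with the analytic score, started
from least-squares coefficients of the link-transformed responses, then
polished by Newton steps using the analytic observed information.

A small family abstraction lets the same engine, prediction, and
diagnostic machinery drive the benchmark regressions (Kumaraswamy,
unit-Weibull, beta) defined in :mod:`ubxii.competitors`; those families
fall back to numerical derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from . import distribution as dist
from .distribution import _check_unit, _log_t, _log_w
from .links import LinkFunction, link_bundle

__all__ = [
    "RegressionModel",
    "RegressionFit",
    "Family",
    "UBXII_FAMILY",
    "reg_loglik",
    "reg_score",
    "reg_observed_info",
    "reg_fit",
    "fit_family",
    "predict",
    "tau_profile",
]

_Q_EPS = 1e-12
_PENALTY = 1e10
_LOG_AUX_BOUND = 35.0    # |log aux| beyond this is treated as out of bounds


@dataclass
class RegressionModel:
    """Response vector, full-rank design matrix (leading intercept), link, tau."""

    y: np.ndarray
    X: np.ndarray
    link: LinkFunction
    tau: float = 0.5
    response_name: str = "y"
    covariate_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.y = _check_unit(np.asarray(self.y, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if isinstance(self.link, str):
            self.link = link_bundle(self.link)
        n, k = self.X.shape
        if self.y.size != n:
            raise ValueError(f"y has {self.y.size} rows but X has {n}")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if np.linalg.matrix_rank(self.X) < k:
            raise ValueError("design matrix X is rank deficient")
        if k >= n:
            raise ValueError(f"need n > k, got n={n}, k={k}")
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if not self.covariate_names:
            self.covariate_names = ["intercept"] + [
                f"x{j + 1}" for j in range(1, k)
            ]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "RegressionModel":
        return RegressionModel(
            self.y[idx], self.X[idx], self.link, self.tau,
            self.response_name, list(self.covariate_names),
        )

    def with_columns(self, extra: np.ndarray, names: Sequence[str]) -> "RegressionModel":
        return RegressionModel(
            self.y, np.column_stack([self.X, extra]), self.link, self.tau,
            self.response_name, list(self.covariate_names) + list(names),
        )


@dataclass(frozen=True)
class Family:
    """A unit-interval regression family with one modeled location parameter
    and one constant auxiliary parameter (shape/dispersion/precision)."""

    name: str
    aux_name: str
    logpdf: Callable     # (y, loc, aux, tau) -> array
    cdf: Callable        # (y, loc, aux, tau) -> array
    aux_start: Callable  # (y) -> float


def _ubxii_logpdf(y, loc, aux, tau):
    lam = -np.log(tau)
    L = _log_t(loc, aux)
    return (
        np.log(aux) + np.log(lam) - np.log(L) - np.log(y)
        + (aux - 1.0) * _log_w(y) - (1.0 + lam / L) * _log_t(y, aux)
    )


def _ubxii_cdf(y, loc, aux, tau):
    return np.exp(np.log(tau) * _log_t(y, aux) / _log_t(loc, aux))


UBXII_FAMILY = Family(
    name="ubxii",
    aux_name="c",
    logpdf=_ubxii_logpdf,
    cdf=_ubxii_cdf,
    aux_start=lambda y: 1.0,
)


@dataclass
class RegressionFit:
    """Maximum-likelihood fit of a unit-interval location regression."""

    model: RegressionModel
    family: Family
    beta: np.ndarray
    aux: float
    loglik: float
    observed_info: np.ndarray    # (k+1)x(k+1), order (beta_1..beta_k, aux)
    std_errors: np.ndarray
    wald_stats: np.ndarray
    p_values: np.ndarray
    ci: np.ndarray
    ci_level: float
    converged: bool
    iterations: int
    score_norm: float

    @property
    def c(self) -> float:
        """Alias for the auxiliary parameter under its UBXII name."""
        return self.aux

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def n_params(self) -> int:
        return self.model.k + 1

    @property
    def theta(self) -> np.ndarray:
        return np.append(self.beta, self.aux)

    def predict(self, X_new=None) -> np.ndarray:
        """Fitted location parameter (the ``tau``-th quantile for quantile
        families, the mean for the beta family)."""
        X = self.model.X if X_new is None else np.atleast_2d(np.asarray(X_new, float))
        if X.shape[1] != self.model.k:
            raise ValueError(
                f"X_new has {X.shape[1]} columns, expected {self.model.k}"
            )
        return np.asarray(self.model.link.g_inv(X @ self.beta))

    def fitted_cdf(self) -> np.ndarray:
        """Fitted-model cdf evaluated at each observed response."""
        return np.asarray(
            self.family.cdf(self.model.y, self.predict(), self.aux, self.model.tau)
        )

    def param_names(self) -> list[str]:
        names = [f"beta{j + 1}" for j in range(self.model.k)]
        return names + [self.family.aux_name]

    def summary(self) -> str:
        rows = [
            f"{self.family.name.upper()} regression "
            f"(link={self.model.link.name}, tau={self.model.tau:g}, "
            f"n={self.n}, k={self.k})",
            f"{'Parameter':<10}{'Estimate':>12}{'Std. Error':>12}"
            f"{'z value':>10}{'p-value':>10}",
        ]
        names = self.param_names()
        for j in range(self.model.k):
            rows.append(
                f"{names[j]:<10}{self.beta[j]:>12.4f}{self.std_errors[j]:>12.4f}"
                f"{self.wald_stats[j]:>10.4f}{self.p_values[j]:>10.4f}"
            )
        rows.append(
            f"{names[-1]:<10}{self.aux:>12.4f}{self.std_errors[-1]:>12.4f}"
            f"{'-':>10}{'-':>10}"
        )
        rows.append(f"log-likelihood = {self.loglik:.4f}  "
                    f"converged = {self.converged}")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        return {
            "family": self.family.name,
            "link": self.model.link.name,
            "tau": self.model.tau,
            "estimates": dict(zip(self.param_names(), self.theta.tolist())),
            "std_errors": self.std_errors.tolist(),
            "wald_stats": self.wald_stats.tolist(),
            "p_values": self.p_values.tolist(),
            "ci": self.ci.tolist(),
            "ci_level": self.ci_level,
            "loglik": self.loglik,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# UBXII analytic likelihood, score, observed information

def _quantiles(model: RegressionModel, beta: np.ndarray) -> np.ndarray:
    q = np.asarray(model.link.g_inv(model.X @ np.asarray(beta, float)))
    return q


def reg_loglik(model: RegressionModel, beta, c: float) -> float:
    """UBXII regression log-likelihood; raises when any fitted quantile
    leaves (0, 1) numerically (the offending index is reported)."""
    q = _quantiles(model, beta)
    bad = ~((q > _Q_EPS) & (q < 1.0 - _Q_EPS))
    if np.any(bad):
        raise FloatingPointError(
            f"fitted quantiles escaped (0,1) at rows {np.flatnonzero(bad).tolist()}"
        )
    return float(np.sum(_ubxii_logpdf(model.y, q, c, model.tau)))


def _ws(model: RegressionModel, beta, c):
    """Per-observation workspace of stable intermediates."""
    y, tau = model.y, model.tau
    lam = -np.log(tau)
    q = _quantiles(model, beta)
    q = np.clip(q, _Q_EPS, 1.0 - _Q_EPS)

    lw = _log_w(y)
    e = special.expit(c * lw)
    a = lw * e                       # d log t(y)/dc
    ap = lw**2 * e * (1.0 - e)
    g = _log_t(y, c)                 # y* in the matrix notation

    lwq = _log_w(q)
    wq = -np.log(q)
    eq = special.expit(c * lwq)
    L = _log_t(q, c)
    A = lwq * eq                     # dL/dc
    Ap = lwq**2 * eq * (1.0 - eq)
    B = -(c / (q * wq)) * eq         # dL/dq
    B_c = -(eq / (q * wq)) * (1.0 + c * lwq * (1.0 - eq))
    B_q = (c * eq / q**2) * (((c - 1.0) - c * eq) / wq**2 + 1.0 / wq)
    return dict(lam=lam, q=q, lw=lw, a=a, ap=ap, g=g, L=L, A=A, Ap=Ap,
                B=B, B_c=B_c, B_q=B_q)


def reg_score(model: RegressionModel, beta, c: float) -> np.ndarray:
    """Analytic score ``(U_beta, U_c)`` of the UBXII regression."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return _reg_score_impl(model, beta, c)


def _reg_score_impl(model, beta, c):
    w = _ws(model, beta, c)
    lam, g, L, A, B = w["lam"], w["g"], w["L"], w["A"], w["B"]
    dl_dq = B * (lam * g / L**2 - 1.0 / L)
    gp = np.asarray(model.link.g_prime(w["q"]))
    U_beta = model.X.T @ (dl_dq / gp)
    y_sharp = (
        1.0 / c + w["lw"] - A / L - w["a"]
        - lam * w["a"] / L + lam * A * g / L**2
    )
    return np.append(U_beta, np.sum(y_sharp))


def reg_observed_info(model: RegressionModel, beta, c: float) -> np.ndarray:
    """Analytic observed information of the UBXII regression, order
    ``(beta, c)``: the negative Hessian of the log-likelihood assembled
    from per-observation second derivatives mapped through the link."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return _reg_observed_info_impl(model, beta, c)


def _reg_observed_info_impl(model, beta, c):
    w = _ws(model, beta, c)
    lam, q, g, L = w["lam"], w["q"], w["g"], w["L"]
    a, ap, A, Ap = w["a"], w["ap"], w["A"], w["Ap"]
    B, B_c, B_q = w["B"], w["B_c"], w["B_q"]
    X = model.X

    gp = np.asarray(model.link.g_prime(q))
    gpp = np.asarray(model.link.g_second(q))

    dl_dq = B * (lam * g / L**2 - 1.0 / L)
    d2l_dq2 = (
        B_q * (lam * g / L**2 - 1.0 / L)
        + B**2 * (1.0 / L**2 - 2.0 * lam * g / L**3)
    )
    # eta-scale second derivative: q = g_inv(eta)
    h = d2l_dq2 / gp**2 - dl_dq * gpp / gp**3
    J_bb = -(X.T * h) @ X

    d2l_dcdq = (
        B_c * (lam * g / L**2 - 1.0 / L)
        + B * (lam * a / L**2 - 2.0 * lam * g * A / L**3 + A / L**2)
    )
    J_bc = -X.T @ (d2l_dcdq / gp)

    dy_sharp_dc = (
        -1.0 / c**2 - (Ap / L - A**2 / L**2) - ap
        - lam * (ap / L - a * A / L**2)
        + lam * ((Ap * g + A * a) / L**2 - 2.0 * A**2 * g / L**3)
    )
    J_cc = -np.sum(dy_sharp_dc)

    J = np.empty((model.k + 1, model.k + 1))
    J[:-1, :-1] = J_bb
    J[:-1, -1] = J_bc
    J[-1, :-1] = J_bc
    J[-1, -1] = J_cc
    return (J + J.T) / 2.0     # enforce exact symmetry against rounding


# ---------------------------------------------------------------------------
# numerical fallbacks for competitor families

def _num_grad(f, x, h=1e-6):
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def _num_hess(f, x, h=1e-4):
    x = np.asarray(x, float)
    d = x.size
    H = np.empty((d, d))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            xi, xj = steps[i], steps[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += xi
                xm[i] -= xi
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / xi**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [xi, xj]
                xpm[i] += xi
                xpm[j] -= xj
                xmp[i] -= xi
                xmp[j] += xj
                xmm[[i, j]] -= [xi, xj]
                H[i, j] = H[j, i] = (
                    (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * xi * xj)
                )
    return H


# ---------------------------------------------------------------------------
# fitting engine

def _family_negll(model: RegressionModel, family: Family):
    """Negative log-likelihood in the internal parameterization
    ``x = (beta, log aux)``; invalid regions get a large finite penalty so
    BFGS line searches back off instead of meeting NaNs."""
    y, tau = model.y, model.tau

    def negll(x):
        with np.errstate(all="ignore"):
            if not np.all(np.isfinite(x)) or abs(x[-1]) > _LOG_AUX_BOUND:
                return _PENALTY + float(np.sum(np.clip(x, -1e8, 1e8) ** 2))
            beta, aux = x[:-1], float(np.exp(x[-1]))
            q = _quantiles(model, beta)
            if not np.all((q > _Q_EPS) & (q < 1.0 - _Q_EPS)):
                return _PENALTY + float(np.sum(x**2))
            val = float(np.sum(family.logpdf(y, q, aux, tau)))
            if not np.isfinite(val):
                return _PENALTY + float(np.sum(x**2))
            return -val

    return negll


def _beta_start(model: RegressionModel) -> np.ndarray:
    z = np.asarray(model.link.g(np.clip(model.y, 1e-6, 1.0 - 1e-6)))
    beta0, *_ = np.linalg.lstsq(model.X, z, rcond=None)
    return beta0


def fit_family(
    model: RegressionModel,
    family: Family = UBXII_FAMILY,
    ci_level: float = 0.95,
    start: Optional[np.ndarray] = None,
) -> RegressionFit:
    """Maximum-likelihood fit of any supported family.

    ``start`` is an optional warm start ``(beta, aux)`` on the natural
    scale (used by leave-one-out refits).
    """
    k = model.k
    if model.n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    negll = _family_negll(model, family)

    analytic = family.name == "ubxii"
    if analytic:
        def jac(x):
            with np.errstate(all="ignore"):
                if not np.all(np.isfinite(x)) or abs(x[-1]) > _LOG_AUX_BOUND:
                    return 2.0 * np.clip(np.nan_to_num(x), -1e8, 1e8)
                beta, aux = x[:-1], float(np.exp(x[-1]))
                q = _quantiles(model, beta)
                if not np.all((q > _Q_EPS) & (q < 1.0 - _Q_EPS)):
                    return 2.0 * x
                u = reg_score(model, beta, aux)
                u[-1] *= aux          # chain rule for log-scale aux
                if not np.all(np.isfinite(u)):
                    return 2.0 * x
                return -u
    else:
        jac = lambda x: _num_grad(negll, x)

    if start is None:
        x0 = np.append(_beta_start(model), np.log(family.aux_start(model.y)))
    else:
        x0 = np.append(np.asarray(start[:-1], float), np.log(start[-1]))

    res = optimize.minimize(
        negll, x0, jac=jac, method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    x = res.x
    n_iter = int(res.nit)

    if analytic:
        # Newton polish with the analytic Hessian for a sharp optimum
        for _ in range(25):
            beta, aux = x[:-1], float(np.exp(x[-1]))
            u = reg_score(model, beta, aux)
            if not np.all(np.isfinite(u)) or np.max(np.abs(u)) <= 1e-8:
                break
            J = reg_observed_info(model, beta, aux)
            # map to internal scale (last coordinate is log aux)
            s = np.ones(k + 1)
            s[-1] = aux
            u_int = u * s
            J_int = J * np.outer(s, s)
            J_int[-1, -1] -= u[-1] * aux    # curvature of the log transform
            try:
                step = np.linalg.solve(J_int, u_int)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            f_cur = negll(x)
            if negll(x + step) <= f_cur + 1e-12:
                x = x + step
                n_iter += 1
            elif negll(x + 0.5 * step) < f_cur:
                x = x + 0.5 * step
                n_iter += 1
            else:
                break

    beta_hat = x[:-1]
    aux_hat = float(np.exp(x[-1]))
    ll = -negll(x)

    if analytic:
        u = reg_score(model, beta_hat, aux_hat)
        info = reg_observed_info(model, beta_hat, aux_hat)
    else:
        theta = np.append(beta_hat, aux_hat)

        def negll_nat(t):
            return negll(np.append(t[:-1], np.log(t[-1])))

        u = -_num_grad(negll_nat, theta)
        info = _num_hess(negll_nat, theta)

    score_norm = float(np.max(np.abs(u)))
    converged = bool(np.isfinite(ll)) and score_norm <= 1e-5 * max(1.0, abs(ll))

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k + 1, np.nan)
        converged = False

    theta_hat = np.append(beta_hat, aux_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = theta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci = np.column_stack([theta_hat - z * se, theta_hat + z * se])

    return RegressionFit(
        model=model, family=family,
        beta=beta_hat, aux=aux_hat, loglik=ll,
        observed_info=info, std_errors=se,
        wald_stats=wald, p_values=pvals, ci=ci, ci_level=ci_level,
        converged=converged, iterations=n_iter, score_norm=score_norm,
    )


def reg_fit(model: RegressionModel, ci_level: float = 0.95,
            start: Optional[np.ndarray] = None) -> RegressionFit:
    """UBXII quantile-regression fit (analytic score and information)."""
    return fit_family(model, UBXII_FAMILY, ci_level=ci_level, start=start)


def predict(fit: RegressionFit, X_new=None) -> np.ndarray:
    """Fitted ``tau``-th quantiles at new design rows."""
    return fit.predict(X_new)


def tau_profile(model: RegressionModel, taus=None,
                family: Family = UBXII_FAMILY, ci_level: float = 0.95):
    """Refit the regression over a grid of ``tau`` values.

    Returns a :class:`pandas.DataFrame` with one row per (tau, parameter):
    estimate, standard error, and pointwise confidence limits.
    """
    import pandas as pd

    if taus is None:
        taus = np.round(np.arange(0.1, 0.95, 0.1), 2)
    rows = []
    for tau in taus:
        m = RegressionModel(model.y, model.X, model.link, float(tau),
                            model.response_name, list(model.covariate_names))
        f = fit_family(m, family, ci_level=ci_level)
        for name, est, se, (lo, hi) in zip(
            f.param_names(), f.theta, f.std_errors, f.ci
        ):
            rows.append({
                "tau": float(tau), "parameter": name, "estimate": est,
                "std_error": se, "ci_low": lo, "ci_high": hi,
                "converged": f.converged,
            })
    return pd.DataFrame(rows)
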