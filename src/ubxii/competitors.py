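"""Benchmark regressions for unit-interval responses.

Three classical families, each with one modeled location parameter (logit
link) and one constant second parameter:

* Kumaraswamy in its median--dispersion parameterization ``(omega, d_p)``;
* unit-Weibull in its quantile parameterization ``(q, gamma)`` with
  ``tau = 0.5`` (median regression);
* beta in the mean--precision parameterization ``(mu, phi)``.

They share the fitting engine, prediction, and diagnostics of
:mod:`ubxii.regression`; scores and Hessians are obtained numerically.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .regression import (Family, RegressionFit, RegressionModel,
                         UBXII_FAMILY, fit_family)

__all__ = [
    "kw_pdf", "kw_cdf", "kw_qf",
    "uw_pdf", "uw_cdf", "uw_qf",
    "beta_pdf",
    "KW_FAMILY", "UW_FAMILY", "BETA_FAMILY", "FAMILIES",
    "fit_competitor",
]


# ---------------------------------------------------------------------------
# Kumaraswamy, median parameterization: F(y) = 1 - (1 - y^{1/d_p})^{b},
# b = log(0.5) / log(1 - omega^{1/d_p}) so that the median is omega.

def _kw_b(omega, d_p):
    return np.log(0.5) / np.log(-np.expm1(np.log(omega) / d_p))


def kw_logpdf(y, omega, d_p, tau=None):
    a = 1.0 / d_p
    b = _kw_b(omega, d_p)
    log_ya = a * np.log(y)
    return (
        np.log(a) + np.log(b) + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log(-np.expm1(log_ya))
    )


def kw_pdf(y, omega, d_p, tau=None):
    return np.exp(kw_logpdf(y, omega, d_p))


def kw_cdf(y, omega, d_p, tau=None):
    b = _kw_b(omega, d_p)
    return -np.expm1(b * np.log(-np.expm1(np.log(y) / d_p)))


def kw_qf(u, omega, d_p):
    b = _kw_b(omega, d_p)
    return np.exp(d_p * np.log(-np.expm1(np.log1p(-u) / b)))


# ---------------------------------------------------------------------------
# unit-Weibull, quantile parameterization: F(y) = tau^{(log y / log q)^gamma}

def uw_logpdf(y, q, gamma, tau=0.5):
    ratio = np.log(y) / np.log(q)
    return (
        np.log(gamma) - np.log(y) + np.log(np.log(tau) / np.log(q))
        + (gamma - 1.0) * np.log(ratio) + ratio**gamma * np.log(tau)
    )


def uw_pdf(y, q, gamma, tau=0.5):
    return np.exp(uw_logpdf(y, q, gamma, tau))


def uw_cdf(y, q, gamma, tau=0.5):
    return np.exp((np.log(y) / np.log(q)) ** gamma * np.log(tau))


def uw_qf(u, q, gamma, tau=0.5):
    return np.exp(np.log(q) * (np.log(u) / np.log(tau)) ** (1.0 / gamma))


# ---------------------------------------------------------------------------
# beta, mean--precision parameterization: shapes (mu*phi, (1-mu)*phi)

def beta_logpdf(y, mu, phi, tau=None):
    return stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi)


def beta_pdf(y, mu, phi, tau=None):
    return np.exp(beta_logpdf(y, mu, phi))


def beta_cdf(y, mu, phi, tau=None):
    return stats.beta.cdf(y, mu * phi, (1.0 - mu) * phi)


def _beta_phi_start(y):
    # method-of-moments precision: var = mu(1-mu)/(1+phi)
    mu = float(np.mean(y))
    v = float(np.var(y))
    phi = mu * (1.0 - mu) / max(v, 1e-8) - 1.0
    return max(phi, 0.5)


KW_FAMILY = Family("kw", "d_p", kw_logpdf, kw_cdf, lambda y: 1.0)
UW_FAMILY = Family("uw", "gamma", uw_logpdf, uw_cdf, lambda y: 1.0)
BETA_FAMILY = Family("beta", "phi", beta_logpdf, beta_cdf, _beta_phi_start)

FAMILIES = {
    "ubxii": UBXII_FAMILY,
    "kw": KW_FAMILY,
    "uw": UW_FAMILY,
    "beta": BETA_FAMILY,
}


def fit_competitor(family: str, model: RegressionModel,
                   ci_level: float = 0.95) -> RegressionFit:
    """Fit one of the benchmark regressions (``kw``, ``uw``, ``beta``)
    — or ``ubxii`` itself — on the same model specification."""
    try:
        fam = FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose one of {sorted(FAMILIES)}"
        ) from None
    return fit_family(model, fam, ci_level=ci_level)
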