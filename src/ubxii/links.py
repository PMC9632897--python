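"""Link functions mapping the unit interval onto the real line.

Each link bundles the map ``g``, its inverse, and its first two
derivatives, which the regression score and observed information need.
All five links are strictly monotone and twice differentiable on (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats

__all__ = ["LinkFunction", "link_bundle", "LINKS"]


@dataclass(frozen=True)
class LinkFunction:
    name: str
    g: Callable          # (0,1) -> R
    g_inv: Callable      # R -> (0,1)
    g_prime: Callable    # g'
    g_second: Callable   # g''


def _logit() -> LinkFunction:
    return LinkFunction(
        "logit",
        g=special.logit,
        g_inv=special.expit,
        g_prime=lambda q: 1.0 / (q * (1.0 - q)),
        g_second=lambda q: (2.0 * q - 1.0) / (q * (1.0 - q)) ** 2,
    )


def _probit() -> LinkFunction:
    phi = stats.norm.pdf

    def second(q):
        z = stats.norm.ppf(q)
        return z / phi(z) ** 2

    return LinkFunction(
        "probit",
        g=stats.norm.ppf,
        g_inv=stats.norm.cdf,
        g_prime=lambda q: 1.0 / phi(stats.norm.ppf(q)),
        g_second=second,
    )


def _cloglog() -> LinkFunction:
    # g(q) = log(-log(1-q))
    def prime(q):
        return -1.0 / ((1.0 - q) * np.log1p(-q))

    def second(q):
        u = -np.log1p(-q)
        return (u - 1.0) / ((1.0 - q) ** 2 * u**2)

    return LinkFunction(
        "cloglog",
        g=lambda q: np.log(-np.log1p(-q)),
        g_inv=lambda eta: -np.expm1(-np.exp(eta)),
        g_prime=prime,
        g_second=second,
    )


def _loglog() -> LinkFunction:
    # g(q) = -log(-log q)
    def prime(q):
        return -1.0 / (q * np.log(q))

    def second(q):
        w = -np.log(q)
        return (1.0 - w) / (q**2 * w**2)

    return LinkFunction(
        "loglog",
        g=lambda q: -np.log(-np.log(q)),
        g_inv=lambda eta: np.exp(-np.exp(-eta)),
        g_prime=prime,
        g_second=second,
    )


def _cauchy() -> LinkFunction:
    def g(q):
        return np.tan(np.pi * (q - 0.5))

    return LinkFunction(
        "cauchy",
        g=g,
        g_inv=lambda eta: 0.5 + np.arctan(eta) / np.pi,
        g_prime=lambda q: np.pi * (1.0 + g(q) ** 2),
        g_second=lambda q: 2.0 * np.pi**2 * g(q) * (1.0 + g(q) ** 2),
    )


LINKS = {
    "logit": _logit(),
    "probit": _probit(),
    "cloglog": _cloglog(),
    "loglog": _loglog(),
    "cauchy": _cauchy(),
}


def link_bundle(name: str) -> LinkFunction:
    """Return the named link; raises for unsupported names."""
    try:
        return LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; choose one of {sorted(LINKS)}"
        ) from None
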