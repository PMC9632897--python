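"""Independent numerical oracles used by the tests.

Deliberately kept separate from the library's own numerics: plain
central differences and textbook-style direct arithmetic, so agreement
with the analytic code paths is a genuine cross-check.
"""

import math

import numpy as np


def fd_grad(f, x, h=1e-6):
    """Central-difference gradient with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        s = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += s
        xm[i] -= s
        g[i] = (f(xp) - f(xm)) / (2.0 * s)
    return g


def fd_hess(f, x, h=1e-4):
    """Central-difference Hessian (full cross-difference stencil)."""
    x = np.asarray(x, dtype=float)
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            si = h * max(1.0, abs(x[i]))
            sj = h * max(1.0, abs(x[j]))
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[i] += si
            xpp[j] += sj
            xpm[i] += si
            xpm[j] -= sj
            xmp[i] -= si
            xmp[j] += sj
            xmm[i] -= si
            xmm[j] -= sj
            H[i, j] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * si * sj)
    return H


def direct_cdf_shape(y, c, d):
    """Textbook arithmetic for the (c, d) cdf."""
    return (1.0 + (-math.log(y)) ** c) ** (-d)


def direct_cdf_quantile(y, c, q, tau):
    """Textbook arithmetic for the quantile-parameterized cdf."""
    return (1.0 + (-math.log(y)) ** c) ** (
        math.log(tau) / math.log(1.0 + (-math.log(q)) ** c)
    )


def direct_pdf_quantile(y, c, q, tau):
    """Textbook arithmetic for the quantile-parameterized density."""
    t_y = 1.0 + (-math.log(y)) ** c
    L = math.log(1.0 + (-math.log(q)) ** c)
    return (
        (-math.log(tau)) * c * (-math.log(y)) ** (c - 1.0)
        / (y * L) * t_y ** (math.log(tau) / L - 1.0)
    )
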