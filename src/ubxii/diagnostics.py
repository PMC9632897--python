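"""Diagnostics, model selection, and influence measures for fitted
unit-interval regressions.

Covers: randomized-normal (quantile) residuals, Anderson--Darling
normality check of those residuals, a RESET-like likelihood-ratio
misspecification test (powers of the fitted location added as testing
covariates), the generalized pseudo-R², AIC/BIC, leave-one-out
cross-validation, and generalized Cook distances with the 4/n
influence threshold.

Everything operates on :class:`~ubxii.regression.RegressionFit` objects,
so the same report works for the UBXII regression and for the
Kumaraswamy / unit-Weibull / beta benchmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .regression import RegressionFit, RegressionModel, fit_family

__all__ = [
    "DiagnosticsReport",
    "quantile_residuals",
    "ad_normality_test",
    "reset_test",
    "pseudo_r2",
    "information_criteria",
    "loocv",
    "cook_distances",
    "diagnose",
]

_RESID_CLIP = 1e-12


@dataclass
class DiagnosticsReport:
    residuals: np.ndarray
    ad_stat: float
    ad_pvalue: float
    reset_stat: float
    reset_pvalue: float
    r2g: float
    aic: float
    bic: float
    cv_n: float
    per_obs_mse: np.ndarray
    cook: np.ndarray
    cook_threshold: float

    def to_dict(self) -> dict:
        return {
            "ad_stat": self.ad_stat,
            "ad_pvalue": self.ad_pvalue,
            "reset_stat": self.reset_stat,
            "reset_pvalue": self.reset_pvalue,
            "r2g": self.r2g,
            "aic": self.aic,
            "bic": self.bic,
            "cv_n": self.cv_n,
            "cook_threshold": self.cook_threshold,
            "max_cook": float(np.max(self.cook)),
            "n_influential": int(np.sum(self.cook > self.cook_threshold)),
        }

    def per_observation_frame(self, fit: RegressionFit):
        import pandas as pd

        return pd.DataFrame({
            "y": fit.model.y,
            "fitted": fit.predict(),
            "residual": self.residuals,
            "cook": self.cook,
            "mse": self.per_obs_mse,
        })


def quantile_residuals(fit: RegressionFit) -> np.ndarray:
    """Standard-normal quantiles of the fitted cdf at each observation.

    Under a correctly specified model these are (approximately) i.i.d.
    standard normal.  Fitted cdf values that underflow to 0 or 1 are
    clipped with a warning rather than producing infinities.
    """
    F = fit.fitted_cdf()
    if np.any(F <= 0.0) or np.any(F >= 1.0):
        warnings.warn("fitted cdf values at 0/1 clipped for residuals",
                      RuntimeWarning, stacklevel=2)
    return stats.norm.ppf(np.clip(F, _RESID_CLIP, 1.0 - _RESID_CLIP))


def ad_normality_test(residuals) -> tuple[float, float]:
    """Anderson--Darling composite normality test (mean and variance
    estimated) of a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 8:
        raise ValueError(f"need at least 8 residuals, got {r.size}")
    stat, pval = normal_ad(r)
    return float(stat), float(pval)


def reset_test(fit: RegressionFit) -> tuple[float, float]:
    """RESET-like misspecification test.

    Adds the squared and cubed fitted locations as testing covariates,
    refits with all parameters free, and compares by a likelihood-ratio
    statistic against chi-square with 2 degrees of freedom.  Rejection
    signals an inadequate functional form.
    """
    q_hat = fit.predict()
    T = np.column_stack([q_hat**2, q_hat**3])
    augmented = fit.model.with_columns(T, ["_reset_sq", "_reset_cube"])
    start = np.concatenate([fit.beta, [0.0, 0.0], [fit.aux]])
    aug_fit = fit_family(augmented, fit.family, start=start)
    if not aug_fit.converged:
        raise RuntimeError("augmented RESET regression did not converge")
    omega = max(2.0 * (aug_fit.loglik - fit.loglik), 0.0)
    pval = float(stats.chi2.sf(omega, df=2))
    return float(omega), pval


def pseudo_r2(fit: RegressionFit, null_fit: RegressionFit | None = None) -> float:
    """Generalized pseudo-R²: ``1 - exp(-2/n * (l_full - l_null))``."""
    if null_fit is None:
        null_fit = _null_fit(fit)
    if null_fit.model.n != fit.model.n or not np.allclose(
        null_fit.model.y, fit.model.y
    ):
        raise ValueError("null fit must be on the same data")
    n = fit.model.n
    return float(1.0 - np.exp(-2.0 / n * (fit.loglik - null_fit.loglik)))


def _null_fit(fit: RegressionFit) -> RegressionFit:
    m = fit.model
    null_model = RegressionModel(
        m.y, np.ones((m.n, 1)), m.link, m.tau, m.response_name, ["intercept"],
    )
    return fit_family(null_model, fit.family)


def information_criteria(fit: RegressionFit) -> tuple[float, float]:
    """AIC = 2(p - l) and BIC = p log n - 2 l, with p = k + 1."""
    p = fit.n_params
    aic = 2.0 * (p - fit.loglik)
    bic = p * np.log(fit.n) - 2.0 * fit.loglik
    return float(aic), float(bic)


def _leave_one_out_fits(fit: RegressionFit):
    """Yield (i, refit-without-row-i); warm-started at the full-data
    optimum, retried cold on failure."""
    m = fit.model
    warm = np.append(fit.beta, fit.aux)
    for i in range(m.n):
        idx = np.arange(m.n) != i
        sub = m.subset(idx)
        try:
            f_i = fit_family(sub, fit.family, start=warm)
            if not f_i.converged:
                f_i = fit_family(sub, fit.family)
        except Exception:
            f_i = fit_family(sub, fit.family)
        yield i, f_i


def loocv(fit: RegressionFit) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation estimate of the prediction error.

    For each row i, refit on the other n-1 rows and predict the held-out
    response by the fitted location; ``CV(n)`` is the mean of the n
    squared errors.  Folds whose refit fails to converge are excluded
    with a warning.
    """
    m = fit.model
    errors = np.full(m.n, np.nan)
    for i, f_i in _leave_one_out_fits(fit):
        if f_i.converged:
            y_hat = float(f_i.predict(m.X[i:i + 1])[0])
            errors[i] = (m.y[i] - y_hat) ** 2
    bad = np.isnan(errors)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} leave-one-out folds excluded (non-convergence)",
            RuntimeWarning, stacklevel=2,
        )
    return float(np.nanmean(errors)), errors


def cook_distances(fit: RegressionFit) -> np.ndarray:
    """Generalized Cook distances.

    ``GD_i`` is the quadratic form of the case-deletion parameter shift
    in the metric of the full-fit observed information; observations with
    ``GD_i > 4/n`` are flagged as influential.
    """
    theta = fit.theta
    J = fit.observed_info
    gd = np.full(fit.model.n, np.nan)
    for i, f_i in _leave_one_out_fits(fit):
        delta = f_i.theta - theta
        gd[i] = float(delta @ J @ delta)
    return gd


def plot_diagnostics(fit: RegressionFit, report: DiagnosticsReport,
                     path_prefix: str) -> list[str]:
    """Write the residual QQ-plot and the Cook-distance index plot as PNGs
    (requires matplotlib); returns the paths written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = fit.model.n
    written = []

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    r = np.sort(report.residuals)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    ax.scatter(theo, r, s=12)
    lim = [min(theo.min(), r.min()), max(theo.max(), r.max())]
    ax.plot(lim, lim, color="red", lw=1)
    ax.set_xlabel("theoretical normal quantiles")
    ax.set_ylabel("quantile residuals")
    fig.tight_layout()
    qq_path = f"{path_prefix}_qq.png"
    fig.savefig(qq_path, dpi=120)
    plt.close(fig)
    written.append(qq_path)

    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.stem(np.arange(1, n + 1), report.cook)
    ax.axhline(report.cook_threshold, color="red", ls="--", lw=1,
               label="4/n threshold")
    ax.set_xlabel("observation")
    ax.set_ylabel("generalized Cook distance")
    ax.legend()
    fig.tight_layout()
    cook_path = f"{path_prefix}_cook.png"
    fig.savefig(cook_path, dpi=120)
    plt.close(fig)
    written.append(cook_path)
    return written


def diagnose(fit: RegressionFit, null_fit: RegressionFit | None = None,
             compute_loocv: bool = True,
             compute_cook: bool = True) -> DiagnosticsReport:
    """Assemble the full diagnostics report for a converged fit."""
    r = quantile_residuals(fit)
    ad_stat, ad_p = ad_normality_test(r)
    reset_stat, reset_p = reset_test(fit)
    r2 = pseudo_r2(fit, null_fit)
    aic, bic = information_criteria(fit)
    n = fit.model.n
    if compute_loocv:
        cv, per_mse = loocv(fit)
    else:
        cv, per_mse = np.nan, np.full(n, np.nan)
    cook = cook_distances(fit) if compute_cook else np.full(n, np.nan)
    return DiagnosticsReport(
        residuals=r, ad_stat=ad_stat, ad_pvalue=ad_p,
        reset_stat=reset_stat, reset_pvalue=reset_p,
        r2g=r2, aic=aic, bic=bic, cv_n=cv, per_obs_mse=per_mse,
        cook=cook, cook_threshold=4.0 / n,
    )
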