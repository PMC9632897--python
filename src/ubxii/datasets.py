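"""Data ingestion and the packaged example dataset.

The packaged example, ``dropout_synthetic.csv``, is a SYNTHETIC stand-in
for the dropout-proportion study data (77 Brazilian undergraduate
animal-science courses; response = dropout proportion over 2009-2017,
covariates = morning-shift vacancies ``x2``, accessibility dummy ``x3``,
night-shift dummy ``x4``).  The original supplementary file is not
redistributable here, so the packaged table was generated once by
:func:`synthesize_fixture` from the published fitted coefficients, with
covariates drawn to mimic the reported structure of the real ones.  Its
role is to exercise the full modeling pipeline on realistically shaped
data, not to reproduce the original study's numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import distribution as dist
from .links import link_bundle
from .regression import RegressionModel

__all__ = ["Dataset", "load_dataset", "load_dropout", "synthesize_fixture",
           "DROPOUT_RESPONSE", "DROPOUT_COVARIATES"]

DROPOUT_RESPONSE = "y"
DROPOUT_COVARIATES = ("x2", "x3", "x4")

# published fitted coefficients of the dropout median regression
# (intercept, vacancies, accessibility, night shift) and shape c —
# the generating values of the packaged synthetic stand-in
DROPOUT_FIT_BETA = (-0.0509, 0.0082, 0.5389, 0.8310)
DROPOUT_FIT_C = 2.3780


@dataclass
class Dataset:
    """Validated modeling table: response in (0, 1) plus named covariates."""

    table: pd.DataFrame
    response: str
    covariates: Sequence[str]
    provenance: str = "user"     # packaged | user | synthetic

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table[self.response].to_numpy(dtype=float)

    def design_matrix(self) -> np.ndarray:
        X = self.table[list(self.covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n), X])

    def to_model(self, link="logit", tau: float = 0.5) -> RegressionModel:
        return RegressionModel(
            self.y, self.design_matrix(), link_bundle(link) if isinstance(link, str) else link,
            tau, self.response, ["intercept", *self.covariates],
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _validate(table: pd.DataFrame, response: str,
              covariates: Sequence[str]) -> None:
    missing = [c for c in (response, *covariates) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    cols = table[[response, *covariates]]
    if cols.isna().any().any():
        bad = cols.index[cols.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows: {bad}")
    y = table[response].to_numpy(dtype=float)
    bad = np.flatnonzero(~((y > 0.0) & (y < 1.0)))
    if bad.size:
        raise ValueError(
            f"response {response!r} must lie strictly inside (0, 1); "
            f"offending rows: {bad.tolist()}"
        )


def load_dataset(path, response: str = DROPOUT_RESPONSE,
                 covariates: Sequence[str] = DROPOUT_COVARIATES,
                 provenance: str = "user") -> Dataset:
    """Load and validate a CSV with a unit-interval response column."""
    table = pd.read_csv(path)
    _validate(table, response, covariates)
    return Dataset(table, response, list(covariates), provenance)


def load_dropout() -> Dataset:
    """The packaged synthetic stand-in for the dropout study data."""
    ref = importlib.resources.files("ubxii").joinpath(
        "data/dropout_synthetic.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return load_dataset(path, provenance="synthetic")


def synthesize_fixture(
    n: int = 77,
    beta: Sequence[float] = DROPOUT_FIT_BETA,
    c: float = DROPOUT_FIT_C,
    tau: float = 0.5,
    seed=12345,
) -> Dataset:
    """Generate a synthetic dataset shaped like the dropout study data.

    Covariates emulate the reported structure of the real ones: ``x2`` is
    a right-skewed non-negative count with many zeros (morning-shift
    vacancies: zero with probability 0.55, otherwise a rounded
    exponential of mean 32, capped at 120), and ``x3``/``x4`` are
    Bernoulli dummies (accessibility, rate 0.6; night shift, rate 0.25).
    Responses are drawn by inversion from the UBXII quantile regression
    at the given coefficients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    x2 = np.where(
        rng.uniform(size=n) < 0.55,
        0.0,
        np.clip(np.round(rng.exponential(scale=32.0, size=n)), 1.0, 120.0),
    )
    x3 = (rng.uniform(size=n) < 0.60).astype(float)
    x4 = (rng.uniform(size=n) < 0.25).astype(float)
    X = np.column_stack([np.ones(n), x2, x3, x4])
    if beta.size != 4:
        raise ValueError("beta must have 4 components (intercept + 3 covariates)")
    link = link_bundle("logit")
    q = link.g_inv(X @ beta)
    u = rng.uniform(size=n)
    L = np.logaddexp(0.0, c * np.log(-np.log(q)))
    y = np.exp(-np.exp(np.log(np.expm1(np.log(u) * L / np.log(tau))) / c))
    table = pd.DataFrame({
        "course_id": np.arange(1, n + 1),
        "y": y, "x2": x2, "x3": x3, "x4": x4,
    })
    return Dataset(table, DROPOUT_RESPONSE, list(DROPOUT_COVARIATES),
                   provenance="synthetic")
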