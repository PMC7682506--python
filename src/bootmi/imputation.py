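"""Proper (Bayesian) imputation of a single continuous outcome.

Two imputers are provided, both producing M completed datasets:

``mar_normal``
    Normal linear-regression imputation under missing-at-random. For each
    imputation the regression of the outcome on the predictors among complete
    rows yields a fresh posterior draw under the standard noninformative
    prior: sigma^2 is drawn as RSS / chi^2(n_obs - p) and beta | sigma^2 is
    multivariate normal around the OLS fit with covariance
    sigma^2 (X'X)^{-1}. Missing outcomes are filled with the drawn conditional
    mean plus Normal(0, sigma^2) noise, so between-imputation variability
    reflects parameter uncertainty ("proper" imputation).

``jump_to_reference``
    Reference-based imputation for a two-arm trial with a single
    post-baseline outcome. Posterior parameters are drawn from the
    control-arm (treatment = 0) regression of outcome on the baseline
    predictors, and *all* missing outcomes — in either arm — are imputed from
    that control-arm conditional distribution, so missing active-arm
    outcomes "jump to reference". This deliberately assumes more than the
    analyst's model does, which is what makes it uncongenial with a standard
    treatment-effect analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from ._rand import as_generator
from .data import Dataset
from .exceptions import ImputationError, SpecError

METHODS = ("mar_normal", "jump_to_reference")


@dataclass(frozen=True)
class ImputationSpec:
    """Imputation model description.

    ``treatment_column`` is required (and must be binary) for
    ``jump_to_reference``; for that method ``predictors`` are the baseline
    covariates of the control-arm model and must not include the treatment
    indicator.
    """

    outcome: str
    predictors: tuple[str, ...]
    method: str = "mar_normal"
    treatment_column: str | None = None
    M: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.method not in METHODS:
            raise SpecError(f"unknown imputation method {self.method!r}; expected one of {METHODS}")
        if self.outcome in self.predictors:
            raise SpecError("outcome cannot be its own predictor")
        if self.M < 1:
            raise SpecError("M must be >= 1")
        if self.method == "jump_to_reference":
            if self.treatment_column is None:
                raise SpecError("jump_to_reference requires a treatment_column")
            if self.treatment_column in self.predictors:
                raise SpecError("treatment_column cannot be a baseline predictor")


def _impute_core(y: np.ndarray, X: np.ndarray, fit_mask: np.ndarray,
                 fill_mask: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """Completed outcome vectors (M, n) from M independent posterior draws.

    The model is fitted to rows in ``fit_mask`` and missing cells in
    ``fill_mask`` are replaced; all other cells are copied through untouched.
    """
    Xc = X[fit_mask]
    yc = y[fit_mask]
    n_fit, p = Xc.shape
    if n_fit < p + 2:
        raise ImputationError(
            f"imputation model has {n_fit} complete rows for {p} coefficients; inestimable")
    G = Xc.T @ Xc
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as exc:
        raise ImputationError("singular imputation design; model not identifiable") from exc
    beta_hat = scipy.linalg.cho_solve((L, True), Xc.T @ yc, check_finite=False)
    resid = yc - Xc @ beta_hat
    rss = float(resid @ resid)
    nu = n_fit - p
    # posterior draws: sigma2 ~ RSS / chi2(nu); beta | sigma2 ~ N(beta_hat, sigma2 G^-1)
    sigma2 = rss / rng.chisquare(nu, size=M)
    sigma = np.sqrt(sigma2)
    z = rng.standard_normal((p, M))
    betas = beta_hat[:, None] + sigma[None, :] * scipy.linalg.solve_triangular(
        L, z, trans="T", lower=True, check_finite=False)
    n_fill = int(fill_mask.sum())
    out = np.tile(y, (M, 1))
    if n_fill:
        mean = X[fill_mask] @ betas                      # (n_fill, M)
        noise = rng.standard_normal((n_fill, M)) * sigma[None, :]
        out[:, fill_mask] = (mean + noise).T
    return out


def _imputation_design(cols: dict[str, np.ndarray], predictors: tuple[str, ...]) -> np.ndarray:
    n = len(next(iter(cols.values())))
    X = np.empty((n, 1 + len(predictors)))
    X[:, 0] = 1.0
    for j, name in enumerate(predictors, start=1):
        X[:, j] = cols[name]
    return X


def _completed_arrays(cols: dict[str, np.ndarray], spec: ImputationSpec, M: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Array-level imputation shared by the public imputers and the
    bootstrap-then-MI loop. ``cols`` must contain the outcome, predictors and
    (for J2R) the treatment column."""
    y = cols[spec.outcome]
    for name in spec.predictors:
        if np.isnan(cols[name]).any():
            raise ImputationError(f"predictor {name!r} has missing values; unsupported pattern")
    miss = np.isnan(y)
    X = _imputation_design(cols, spec.predictors)
    if spec.method == "mar_normal":
        fit_mask = ~miss
    else:
        treat = cols[spec.treatment_column]
        if np.isnan(treat).any():
            raise ImputationError("treatment column has missing values")
        fit_mask = (treat == 0.0) & ~miss
    return _impute_core(y, X, fit_mask, miss, M, rng)


def _impute(data: Dataset, spec: ImputationSpec, rng) -> list[Dataset]:
    rng = as_generator(rng)
    names = {spec.outcome, *spec.predictors}
    if spec.method == "jump_to_reference":
        data.require_binary(spec.treatment_column)
        names.add(spec.treatment_column)
    cols = {name: data.column(name) for name in names}
    completed = _completed_arrays(cols, spec, spec.M, rng)
    return [data.with_column(spec.outcome, completed[m]) for m in range(spec.M)]


def impute_mar_normal(data: Dataset, spec: ImputationSpec, rng=None) -> list[Dataset]:
    """M completed datasets under proper MAR normal-regression imputation."""
    if spec.method != "mar_normal":
        spec = replace(spec, method="mar_normal", treatment_column=None)
    return _impute(data, spec, rng)


def impute_jump_to_reference(data: Dataset, spec: ImputationSpec, rng=None) -> list[Dataset]:
    """M completed datasets with all missing outcomes drawn from the
    control-arm model."""
    if spec.method != "jump_to_reference":
        raise SpecError("spec.method must be 'jump_to_reference'")
    return _impute(data, spec, rng)


def impute(data: Dataset, spec: ImputationSpec, rng=None) -> list[Dataset]:
    """Dispatch on ``spec.method``."""
    if spec.method == "mar_normal":
        return impute_mar_normal(data, spec, rng)
    return impute_jump_to_reference(data, spec, rng)
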