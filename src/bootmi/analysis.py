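"""The analyst's complete-data procedure: OLS for one target coefficient.

The complete-data model is ordinary least squares with an intercept,
homoscedastic model-based variance (denominator n − p), optional restriction
to a subgroup defined by one binary column, and optional pairwise interaction
terms. The point estimate and variance for a single named coefficient are
returned; this is the building block every pooling method in the package
consumes.

Bootstrap layers need very large numbers of refits, so alongside the public
:func:`fit_ols` this module carries batched coefficient-only fitters
(:class:`_AnalysisPlan`, :func:`_bootstrap_coefs`) written on normal equations
and einsum. Their agreement with a reference OLS implementation is asserted in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import Dataset
from .exceptions import EstimationError, SpecError

INTERCEPT = "const"


@dataclass(frozen=True)
class AnalysisSpec:
    """What the analyst fits and which coefficient they care about.

    Parameters
    ----------
    outcome
        Name of the response column.
    covariates
        Columns entering the linear predictor (an intercept is always added).
    target
        Name of the coefficient reported: a covariate, ``"const"``, or an
        interaction label ``"a:b"``.
    subgroup
        Optional ``(column, value)`` pair; the model is fitted only to rows
        where the binary column equals ``value``. Applied after imputation.
    interactions
        Pairs of column names whose products are added as extra columns.
    """

    outcome: str
    covariates: tuple[str, ...]
    target: str
    subgroup: tuple[str, float] | None = None
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions", tuple(tuple(p) for p in self.interactions))
        if self.outcome in self.covariates:
            raise SpecError("outcome cannot appear among covariates")
        names = _coef_names(self)
        if self.target not in names:
            raise SpecError(f"target {self.target!r} not among fitted coefficients {names}")


@dataclass(frozen=True)
class EstimateWithVariance:
    estimate: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise SpecError("variance must be non-negative")


def _coef_names(spec: AnalysisSpec) -> list[str]:
    return [INTERCEPT, *spec.covariates, *(f"{a}:{b}" for a, b in spec.interactions)]


class _AnalysisPlan:
    """Precompiled design layout for repeated fits on raw column arrays.

    The plan knows how to assemble the design matrix from a dict of numpy
    columns, and how to assemble a *batch* of designs when exactly one column
    (the imputed variable) varies across M imputations. Design entries are
    linear in any single column, so the batch is built as
    ``X_m = X_base + imputed_m[:, None] * S`` where S is the per-column
    derivative pattern.
    """

    def __init__(self, spec: AnalysisSpec):
        self.spec = spec
        self.names = _coef_names(spec)
        self.p = len(self.names)
        self.t = self.names.index(spec.target)

    def required_columns(self) -> set[str]:
        cols = {self.spec.outcome, *self.spec.covariates}
        for a, b in self.spec.interactions:
            cols.update((a, b))
        if self.spec.subgroup is not None:
            cols.add(self.spec.subgroup[0])
        return cols

    def rows_mask(self, cols: dict[str, np.ndarray]) -> np.ndarray | None:
        if self.spec.subgroup is None:
            return None
        name, value = self.spec.subgroup
        return cols[name] == value

    def design(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        n = len(cols[self.spec.outcome])
        X = np.empty((n, self.p))
        X[:, 0] = 1.0
        for j, c in enumerate(self.spec.covariates, start=1):
            X[:, j] = cols[c]
        for j, (a, b) in enumerate(self.spec.interactions, start=1 + len(self.spec.covariates)):
            X[:, j] = cols[a] * cols[b]
        return X

    def batched_designs(self, cols: dict[str, np.ndarray], vary: str,
                        values: np.ndarray) -> np.ndarray:
        """Design matrices (M, n, p) when column ``vary`` takes the M rows of
        ``values`` and all other columns are fixed."""
        for a, b in self.spec.interactions:
            if a == vary and b == vary:
                raise SpecError("self-interaction of the imputed column is not supported")
        base_cols = dict(cols)
        base_cols[vary] = np.zeros_like(values[0])
        X0 = self.design(base_cols)
        S = np.zeros_like(X0)
        for j, c in enumerate(self.spec.covariates, start=1):
            if c == vary:
                S[:, j] = 1.0
        for j, (a, b) in enumerate(self.spec.interactions, start=1 + len(self.spec.covariates)):
            if a == vary:
                S[:, j] = cols[b] if b != vary else 0.0
            elif b == vary:
                S[:, j] = cols[a]
        return X0[None, :, :] + values[:, :, None] * S[None, :, :]


def _fit_arrays(X: np.ndarray, y: np.ndarray, t: int) -> EstimateWithVariance:
    """OLS coefficient ``t`` and its homoscedastic model-based variance."""
    n, p = X.shape
    if n < p + 1:  # at least one residual degree of freedom
        raise EstimationError(f"only {n} rows for {p} coefficients")
    G = X.T @ X
    try:
        cf = scipy.linalg.cho_factor(G, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise EstimationError("collinear (rank-deficient) design") from exc
    beta = scipy.linalg.cho_solve(cf, X.T @ y, check_finite=False)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    e = np.zeros(p)
    e[t] = 1.0
    g_tt = float(scipy.linalg.cho_solve(cf, e, check_finite=False)[t])
    return EstimateWithVariance(float(beta[t]), max(s2 * g_tt, 0.0))


def fit_ols(data: Dataset, spec: AnalysisSpec) -> EstimateWithVariance:
    """Fit the analysis model to complete data and report the target coefficient.

    The data must be complete on the outcome and every column entering the
    design (this is the post-imputation contract). Raises
    :class:`EstimationError` for collinear designs or unusably small
    subgroups.
    """
    plan = _AnalysisPlan(spec)
    names = sorted(plan.required_columns())
    data.require_complete(names)
    cols = {name: data.column(name) for name in names}
    if spec.subgroup is not None:
        data.require_binary(spec.subgroup[0])
    mask = plan.rows_mask(cols)
    if mask is not None:
        if mask.sum() < plan.p + 2:
            raise EstimationError(
                f"subgroup {spec.subgroup} leaves {int(mask.sum())} rows; too few to fit")
        cols = {k: v[mask] for k, v in cols.items()}
    X = plan.design(cols)
    return _fit_arrays(X, cols[spec.outcome], plan.t)


# -- batched bootstrap machinery ------------------------------------------

def _multinomial_weights(n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Row-resampling weights: counts of each original row in each of B
    with-replacement resamples of size n."""
    return rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)


def _solve_batch(G: np.ndarray, r: np.ndarray) -> np.ndarray:
    beta = np.linalg.solve(G, r[..., None])[..., 0]
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError("non-finite batched solution")
    return beta


def _bootstrap_coefs(X: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator,
                     t: int, submask: np.ndarray | None = None,
                     max_retries: int = 10) -> np.ndarray:
    """Target coefficients from B with-replacement row resamples of (X, y).

    Resampling covers all rows; a subgroup restriction is applied afterwards
    by zeroing the weights outside the subgroup, which is identical to
    filtering the resampled table. Singular resamples are redrawn up to
    ``max_retries`` passes, then reported as an :class:`EstimationError`.
    """
    n = len(y)
    p = X.shape[1]
    P = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)  # outer products per row
    W = _multinomial_weights(n, B, rng)
    if submask is not None:
        W *= submask
    for _ in range(max_retries):
        G = (W @ P).reshape(B, p, p)
        r = (W * y) @ X
        try:
            return _solve_batch(G, r)[:, t]
        except np.linalg.LinAlgError:
            # find and redraw the offending resamples only
            bad = []
            for b in range(B):
                try:
                    np.linalg.cholesky(G[b])
                except np.linalg.LinAlgError:
                    bad.append(b)
            if not bad:
                raise
            Wnew = _multinomial_weights(n, len(bad), rng)
            if submask is not None:
                Wnew *= submask
            W[bad] = Wnew
    raise EstimationError(f"singular bootstrap resamples persisted after {max_retries} redraws")
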