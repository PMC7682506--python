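"""Bootstrap first, then multiply impute each resample.

B with-replacement resamples of the *incomplete* data are drawn; each is
independently imputed M times and analysed, giving the clustered grid
theta_bm. Two inferences are built on it:

``boot_mi_percentile``
    The standard percentile bootstrap applied to the MI estimator: interval
    from the empirical percentiles of the per-replicate means
    theta_bar_b = mean_m theta_bm. Asymptotically valid whenever the point
    estimator is consistent — congeniality is not required — but expensive
    (it wants large B *and* moderate M; with M = 1 the intervals are wide and
    over-cover because single-imputation Monte-Carlo noise is resampled into
    the percentiles).

``von_hippel_inference``
    Treat the grid as a one-way random-effects model
    theta_bm = theta_inf + c_b + d_bm with components sigma2_inf (between
    bootstraps, the sampling variance of interest) and sigma2_btw (imputation
    noise within a bootstrap). The one-way ANOVA mean squares give

        sigma2_inf_hat = (MSB - MSW) / M,   sigma2_btw_hat = MSW,

    and the variance of the grand mean theta_bar_BM is estimated by

        Var_hat = (1 + 1/B)(MSB - MSW)/M + MSW/(BM)
                = ((B+1)/(BM)) MSB - MSW/M

    with a t interval on Satterthwaite degrees of freedom. If MSB < MSW the
    component estimates are truncated: sigma2_inf_hat = 0 and sigma2_btw_hat
    set to the total sample variance of the BM estimates, which keeps the
    variance non-negative. Recommended settings: large B with M = 2 — far
    cheaper than percentile Boot MI at equal validity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from ._rand import as_generator
from .analysis import AnalysisSpec, _AnalysisPlan, _solve_batch
from .data import Dataset
from .exceptions import EstimationError, ImputationError, SpecError
from .imputation import ImputationSpec, _impute_core
from .mi_boot import EstimateGrid
from .pooling import PooledInference, t_interval


@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA decomposition of a bootstrap-major grid.

    ``fallback_used`` flags the MSB < MSW truncation, in which case
    ``sigma2_inf`` is 0 and ``sigma2_btw`` is the total sample variance of
    the BM estimates rather than MSW.
    """

    msw: float
    msb: float
    sigma2_inf: float
    sigma2_btw: float
    fallback_used: bool


def _grid_bm(grid) -> np.ndarray:
    if isinstance(grid, EstimateGrid):
        return grid.by_bootstrap()
    return np.asarray(grid, dtype=float)


def anova_components(grid) -> VarianceComponents:
    """ANOVA variance-component estimates from a (B, M) bootstrap-major grid."""
    vals = _grid_bm(grid)
    B, M = vals.shape
    if B < 2:
        raise SpecError("need B >= 2 bootstrap replicates")
    if M < 2:
        raise SpecError("need M >= 2 imputations per replicate (MSW undefined for M = 1)")
    theta_b = vals.mean(axis=1)
    grand = theta_b.mean()
    msb = M * float(((theta_b - grand) ** 2).sum()) / (B - 1)
    msw = float(((vals - theta_b[:, None]) ** 2).sum()) / (B * (M - 1))
    if msb >= msw:
        return VarianceComponents(msw, msb, (msb - msw) / M, msw, False)
    return VarianceComponents(msw, msb, 0.0, float(vals.var(ddof=1)), True)


def von_hippel_variance(msb: float, msw: float, B: int, M: int) -> float:
    """((B+1)/(BM)) MSB - MSW/M, the two displayed forms being identical."""
    return ((B + 1) / (B * M)) * msb - msw / M


def satterthwaite_df(msb: float, msw: float, B: int, M: int) -> float:
    """Satterthwaite df for the von Hippel variance estimator.

    Evaluated as the analytic limit B - 1 when MSW = 0 (both numerator and
    denominator collapse), rather than as 0/0.
    """
    if msw == 0.0:
        return float(B - 1)
    num = von_hippel_variance(msb, msw, B, M) ** 2
    den = ((B + 1) / (B * M)) ** 2 * msb ** 2 / (B - 1) + msw ** 2 / (B * M ** 2 * (M - 1))
    if num == 0.0 or den == 0.0:
        return float(B - 1)
    return num / den


def von_hippel_inference(grid, alpha: float = 0.05) -> PooledInference:
    """Point estimate theta_bar_BM with the ANOVA variance and a
    Satterthwaite-df t interval.

    When the MSB < MSW fallback engages, both the variance and the df formula
    are evaluated with MSB and MSW replaced consistently by the
    fallback-implied components (equal to the total sample variance), which
    reduces the variance to s2_tot/(BM).
    """
    vals = _grid_bm(grid)
    B, M = vals.shape
    vc = anova_components(vals)
    if vc.fallback_used:
        msb_eff = msw_eff = vc.sigma2_btw
    else:
        msb_eff, msw_eff = vc.msb, vc.msw
    variance = max(von_hippel_variance(msb_eff, msw_eff, B, M), 0.0)
    df = satterthwaite_df(msb_eff, msw_eff, B, M)
    estimate = float(vals.mean())
    result = t_interval(estimate, variance, df, alpha, "boot_mi_vonhippel")
    return result


def boot_mi_percentile(grid, alpha: float = 0.05) -> PooledInference:
    """Percentile interval of the per-replicate means theta_bar_b.

    The point estimate is theta_bar_BM (the grand mean); the variance field
    carries the sample variance of the theta_bar_b as a diagnostic.
    """
    vals = _grid_bm(grid)
    if vals.shape[0] < 2:
        raise SpecError("need B >= 2 bootstrap replicates")
    theta_b = vals.mean(axis=1)
    lo, hi = np.quantile(theta_b, [alpha / 2, 1 - alpha / 2])
    estimate = float(theta_b.mean())
    lo = min(float(lo), estimate)
    hi = max(float(hi), estimate)
    return PooledInference(estimate, float(theta_b.var(ddof=1)), math.inf,
                           lo, hi, alpha, "boot_mi_percentile")


class _BootMIRunner:
    """Precompiled state for the resample -> impute -> analyse loop.

    All row-indexed quantities (imputation design, analysis design split into
    a fixed part X0 and the derivative pattern S of the imputed column, the
    subgroup indicator) are built once on the original data; a bootstrap
    replicate then only needs row gathers, one posterior draw and one small
    batched solve. The analysis design is linear in the imputed column, so
    the M completed designs are X0 + completed_m[:, None] * S.
    """

    def __init__(self, data: Dataset, imp: ImputationSpec, ana: AnalysisSpec):
        from .imputation import _imputation_design
        self.imp = imp
        plan = _AnalysisPlan(ana)
        self.plan = plan
        names = plan.required_columns() | {imp.outcome, *imp.predictors}
        if imp.method == "jump_to_reference":
            data.require_binary(imp.treatment_column)
            names.add(imp.treatment_column)
        cols = {name: data.column(name) for name in sorted(names)}
        for name in imp.predictors:
            if np.isnan(cols[name]).any():
                raise ImputationError(f"predictor {name!r} has missing values")
        self.n = data.n
        self.y = cols[imp.outcome]
        self.Ximp = _imputation_design(cols, imp.predictors)
        self.treat = (cols[imp.treatment_column]
                      if imp.method == "jump_to_reference" else None)
        if self.treat is not None and np.isnan(self.treat).any():
            raise ImputationError("treatment column has missing values")
        if plan.spec.subgroup is None:
            self.sub = None
        else:
            name, value = plan.spec.subgroup
            self.sub = cols[name] == value
        self.outcome_imputed = imp.outcome == ana.outcome
        if self.outcome_imputed:
            self.X_ana = plan.design(cols)
        else:
            base = dict(cols)
            base[imp.outcome] = np.zeros(self.n)
            self.X0 = plan.design(base)
            S = np.zeros_like(self.X0)
            spec = plan.spec
            for j, c in enumerate(spec.covariates, start=1):
                if c == imp.outcome:
                    S[:, j] = 1.0
            off = 1 + len(spec.covariates)
            for j, (a, b) in enumerate(spec.interactions, start=off):
                if a == imp.outcome and b == imp.outcome:
                    raise SpecError("self-interaction of the imputed column is unsupported")
                if a == imp.outcome:
                    S[:, j] = cols[b]
                elif b == imp.outcome:
                    S[:, j] = cols[a]
            self.S = S
            self.y_ana = cols[ana.outcome]

    def replicate(self, idx: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
        """Estimates (M,) for one resample given row indices ``idx``."""
        y_b = self.y[idx]
        miss = np.isnan(y_b)
        if self.treat is None:
            fit_mask = ~miss
        else:
            fit_mask = (self.treat[idx] == 0.0) & ~miss
        completed = _impute_core(y_b, self.Ximp[idx], fit_mask, miss, M, rng)
        plan = self.plan
        rows = None if self.sub is None else self.sub[idx]
        if rows is not None and int(rows.sum()) < plan.p + 2:
            raise EstimationError("subgroup too small in this resample")
        if self.outcome_imputed:
            X = self.X_ana[idx]
            Y = completed
            if rows is not None:
                X = X[rows]
                Y = Y[:, rows]
            L = np.linalg.cholesky(X.T @ X)     # LinAlgError caught by caller
            beta = scipy.linalg.cho_solve((L, True), X.T @ Y.T, check_finite=False)
            return beta[plan.t]
        X0 = self.X0[idx]
        S = self.S[idx]
        y = self.y_ana[idx]
        if rows is not None:
            X0, S, y, completed = X0[rows], S[rows], y[rows], completed[:, rows]
        Xs = X0[None, :, :] + completed[:, :, None] * S[None, :, :]
        Xt = Xs.swapaxes(1, 2)
        G = Xt @ Xs
        r = Xt @ y
        return _solve_batch(G, r)[:, plan.t]


def boot_mi_estimates(data: Dataset, imp: ImputationSpec, ana: AnalysisSpec,
                      B: int, M: int, rng=None, max_retries: int = 10) -> EstimateGrid:
    """The full (B, M) grid: resample the incomplete data, impute, analyse.

    Each bootstrap replicate is imputed with fresh, independent posterior
    draws (no sharing across replicates). A replicate on which the imputation
    or analysis model is inestimable (singular design, subgroup collapse) is
    redrawn up to ``max_retries`` times before an :class:`EstimationError` is
    raised; silently dropping replicates would bias B.
    """
    if B < 2 or M < 1:
        raise SpecError("need B >= 2 and M >= 1")
    rng = as_generator(rng)
    imp = replace(imp, M=M)
    runner = _BootMIRunner(data, imp, ana)
    n = data.n
    vals = np.empty((B, M))
    for b in range(B):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = runner.replicate(idx, M, rng)
            except (ImputationError, EstimationError, np.linalg.LinAlgError):
                continue
            break
        else:
            raise EstimationError(
                f"bootstrap replicate kept failing after {max_retries} redraws")
    return EstimateGrid(vals, "bootstrap_major")
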