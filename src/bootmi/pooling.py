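"""Rubin's rules: combine M per-imputation estimates into one inference.

Given per-imputation point estimates theta_m and complete-data variances
W_m, the pooled estimate is the mean theta_bar, and the total variance is

    T = W_bar + (1 + 1/M) * B,    B = sample variance of the theta_m

with W_bar the mean within-imputation variance. Intervals use a
t distribution on Rubin's classical degrees of freedom

    nu = (M - 1) * (1 + W_bar / ((1 + 1/M) B))^2

falling back to the normal quantile when B = 0 (and the small-sample
Barnard-Rubin adjustment deliberately omitted: the package targets
moderate-to-large n where it is immaterial). A plain-normal rule is
available via ``df_method="normal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import SpecError


@dataclass(frozen=True)
class PooledInference:
    """A pooled point estimate with variance, df and a two-sided interval.

    ``alpha`` is the total two-sided error rate (0.05 for a 95% interval);
    ``df`` is +inf where a normal quantile (or a percentile construction with
    no t reference) was used. ``variance`` carries the method's variance
    estimate — for percentile methods this is a diagnostic, not what the
    interval was built from.
    """

    estimate: float
    variance: float
    df: float
    ci_lower: float
    ci_upper: float
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise SpecError("variance must be non-negative")
        if not (self.ci_lower <= self.estimate + 1e-12 and
                self.estimate - 1e-12 <= self.ci_upper):
            raise SpecError("interval must contain the point estimate")

    @property
    def width(self) -> float:
        return self.ci_upper - self.ci_lower

    def covers(self, value: float) -> bool:
        return self.ci_lower <= value <= self.ci_upper


def _critical_value(alpha: float, df: float) -> float:
    if math.isinf(df):
        return float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.t.ppf(1 - alpha / 2, df))


def t_interval(estimate: float, variance: float, df: float, alpha: float,
               method: str) -> PooledInference:
    half = _critical_value(alpha, df) * math.sqrt(variance)
    return PooledInference(estimate, variance, df, estimate - half, estimate + half,
                           alpha, method)


def pool_rubin(estimates, within_vars, alpha: float = 0.05,
               df_method: str = "rubin") -> PooledInference:
    """Pool M estimates and within-imputation variances with Rubin's rules.

    Parameters
    ----------
    estimates, within_vars
        Length-M sequences; ``within_vars`` must be non-negative.
    alpha
        Two-sided error rate of the interval.
    df_method
        ``"rubin"`` (classical df, default) or ``"normal"`` (z quantiles).
    """
    est = np.asarray(estimates, dtype=float)
    wv = np.asarray(within_vars, dtype=float)
    if est.ndim != 1 or est.shape != wv.shape:
        raise SpecError("estimates and within_vars must be equal-length vectors")
    M = est.size
    if M < 2:
        raise SpecError("Rubin's rules need M >= 2 (between-imputation variance undefined)")
    if (wv < 0).any():
        raise SpecError("within-imputation variances must be non-negative")
    if df_method not in ("rubin", "normal"):
        raise SpecError(f"unknown df_method {df_method!r}")

    qbar = float(est.mean())
    B = float(est.var(ddof=1))
    Wbar = float(wv.mean())
    T = Wbar + (1.0 + 1.0 / M) * B
    if df_method == "normal" or B == 0.0:
        df = math.inf
    else:
        ratio = Wbar / ((1.0 + 1.0 / M) * B)
        df = math.inf if ratio > 1e100 else (M - 1) * (1.0 + ratio) ** 2
    return t_interval(qbar, T, df, alpha, "rubin")
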