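"""One entry point per inference method, shared by the CLI and the
simulation engine."""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._rand import as_generator
from .analysis import AnalysisSpec, fit_ols
from .boot_mi import boot_mi_estimates, boot_mi_percentile, von_hippel_inference
from .data import Dataset
from .exceptions import SpecError
from .imputation import ImputationSpec, impute
from .mi_boot import mi_boot_pooled_percentile, mi_boot_rubin
from .pooling import PooledInference, pool_rubin

METHOD_NAMES = (
    "rubin",
    "mi_boot_rubin",
    "mi_boot_pooled",
    "boot_mi_percentile",
    "boot_mi_vonhippel",
)

_NEEDS_B = ("mi_boot_rubin", "mi_boot_pooled", "boot_mi_percentile", "boot_mi_vonhippel")


@dataclass(frozen=True)
class MethodSetting:
    """A method name with its tuning constants (M imputations, B bootstraps,
    two-sided error rate alpha)."""

    name: str
    M: int
    B: int | None = None
    alpha: float = 0.05
    df_method: str = "rubin"

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise SpecError(f"unknown method {self.name!r}; expected one of {METHOD_NAMES}")
        if self.M < 1:
            raise SpecError("M must be >= 1")
        if self.name in _NEEDS_B and (self.B is None or self.B < 2):
            raise SpecError(f"method {self.name!r} needs B >= 2")
        if not 0 < self.alpha < 1:
            raise SpecError("alpha must lie in (0, 1)")

    @property
    def key(self) -> str:
        """Unique label for result tables (the same method may appear with
        different M/B)."""
        if self.B is None:
            return f"{self.name}[M={self.M}]"
        return f"{self.name}[M={self.M},B={self.B}]"


def run_method(data: Dataset, imp: ImputationSpec, ana: AnalysisSpec,
               setting: MethodSetting, rng=None) -> PooledInference:
    """Apply one inference method to one incomplete dataset."""
    rng = as_generator(rng)
    name, M, B, alpha = setting.name, setting.M, setting.B, setting.alpha
    if name == "rubin":
        imputed = impute(data, replace(imp, M=M), rng)
        fits = [fit_ols(d, ana) for d in imputed]
        result = pool_rubin([f.estimate for f in fits], [f.variance for f in fits],
                            alpha, setting.df_method)
        return result
    if name == "mi_boot_rubin":
        return mi_boot_rubin(data, imp, ana, M, B, alpha, rng, df_method=setting.df_method)
    if name == "mi_boot_pooled":
        return mi_boot_pooled_percentile(data, imp, ana, M, B, alpha, rng)
    grid = boot_mi_estimates(data, imp, ana, B, M, rng)
    if name == "boot_mi_percentile":
        return boot_mi_percentile(grid, alpha)
    return von_hippel_inference(grid, alpha)
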