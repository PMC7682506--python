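"""Coverage simulation engine for the two study designs.

Two data-generating scenarios are built in:

* :class:`TrialScenario` — a two-arm randomised trial with a bivariate normal
  (baseline X, outcome Y) pair per arm, fixed-count arm assignment, MCAR
  dropout on Y, and either congenial MAR normal-regression imputation or
  uncongenial jump-to-reference imputation. Analysis: OLS of Y on X and
  treatment Z, treatment coefficient of interest.

* :class:`AnthroScenario` — an anthropometric model (sex; age and height
  jointly normal given sex; weight linear in sex, age, height; log insulin
  index linear in sex, age, weight) with scenario switches that induce
  uncongeniality (subgroup analysis, omitted interaction) or
  misspecification (heteroscedastic errors, log-normal errors). Weight is
  made MCAR; analysis targets the weight coefficient in the insulin-index
  model.

:func:`run_study` replays a scenario ``n_reps`` times, applies every
configured method to the *same* simulated dataset per replication (a master
seed spawns one substream per replication and per method layer), and
summarises coverage, median interval width and the Monte-Carlo standard
error of the coverage estimate.

Under jump-to-reference the estimand of the MI point estimator is not the
generating treatment effect: with Y MCAR at rate p_mis, missing active-arm
outcomes are drawn from the control model, so the completed-data treatment
coefficient converges to (1 - p_mis) * effect. Repeated-sampling coverage is
therefore assessed against that probability limit; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rand import as_generator
from .analysis import AnalysisSpec
from .data import Dataset
from .exceptions import BootmiError, SpecError
from .imputation import ImputationSpec
from .methods import MethodSetting, run_method

ANTHRO_SCENARIOS = ("baseline", "subgroup", "heteroscedastic",
                    "omitted_interaction", "non_normal")


def mc_se(nominal: float, n_reps: int) -> float:
    """Monte-Carlo standard error, in percentage points, of an estimated
    coverage probability: 100 * sqrt(nominal (1 - nominal) / n_reps)."""
    if not 0.0 < nominal < 1.0:
        raise SpecError("nominal coverage must lie in (0, 1)")
    return 100.0 * math.sqrt(nominal * (1.0 - nominal) / n_reps)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialScenario:
    """Two-arm trial generator: (X, Y) bivariate normal with the outcome mean
    shifted by ``treatment_effect`` in the active arm, exact per-arm counts,
    and MCAR missingness on Y."""

    n: int = 500
    arm_size: int = 250
    baseline_mean: float = 2.0
    outcome_mean_control: float = 2.0
    treatment_effect: float = 0.2
    var_x: float = 0.4
    var_y: float = 0.4
    cov_xy: float = 0.2
    missing_prob: float = 0.5
    imputation_method: str = "mar_normal"

    def __post_init__(self) -> None:
        if 2 * self.arm_size != self.n:
            raise SpecError("arm sizes must sum to n (two equal arms)")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise SpecError("missing_prob must lie in [0, 1]")
        cov = np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise SpecError("(X, Y) covariance matrix must be positive definite")

    def generate(self, rng=None) -> Dataset:
        rng = as_generator(rng)
        z = np.repeat([0.0, 1.0], self.arm_size)  # fixed-count randomisation
        cov = np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])
        L = np.linalg.cholesky(cov)
        e = rng.standard_normal((self.n, 2)) @ L.T
        x = self.baseline_mean + e[:, 0]
        y = self.outcome_mean_control + self.treatment_effect * z + e[:, 1]
        y = np.where(rng.random(self.n) < self.missing_prob, np.nan, y)
        return Dataset(pd.DataFrame({"x": x, "y": y, "z": z}))

    def imputation_spec(self, M: int = 5) -> ImputationSpec:
        if self.imputation_method == "jump_to_reference":
            return ImputationSpec("y", ("x",), "jump_to_reference",
                                  treatment_column="z", M=M)
        return ImputationSpec("y", ("x", "z"), "mar_normal", M=M)

    def analysis_spec(self) -> AnalysisSpec:
        return AnalysisSpec("y", ("x", "z"), target="z")

    def true_target(self) -> float:
        """Probability limit of the MI point estimator for the Z coefficient.

        Under MAR imputation this is the generating effect. Under jump to
        reference the imputer replaces missing active-arm outcomes with
        control-model draws, attenuating the completed-data effect to
        (1 - missing_prob) * effect — the method's own estimand, against
        which repeated-sampling coverage is assessed.
        """
        if self.imputation_method == "jump_to_reference":
            return self.treatment_effect * (1.0 - self.missing_prob)
        return self.treatment_effect


@dataclass(frozen=True)
class AnthroScenario:
    """Anthropometric generator with scenario switches.

    The generating model is::

        sex ~ Bernoulli(pi)
        (age, height) | sex ~ N(alpha0 + alpha1 * sex, Sigma)
        weight = iota0 + iota1 sex + iota2 age + iota3 height
                 + eta_sex^lambda * error_W
        loginsindex = beta0 + beta1 sex + beta2 age + theta * weight
                      + eta_sex^omega * error_L

    with eta_sex = 1 for sex 0 and ``eta`` for sex 1, and error scales
    ``sigma_w`` / ``sigma_l``. Scenario switches: ``subgroup`` (weight
    missing in men only, imputation pools sexes, analysis restricted to
    men), ``heteroscedastic`` (eta = 2), ``omitted_interaction`` (analysis
    adds weight x sex, imputation correctly omits it), ``non_normal``
    (errors take a standardised log-normal shape). In the log-normal case
    the exp{N(0, lognormal_sigma^2)} shape is centred and scaled to mean 0
    and variance 1 before multiplying by the error SD, so only the error
    *shape* departs from the baseline.

    The defaults (units: years, cm, kg, log units) are placeholders
    satisfying the scenario-defining constraints — null sex effects
    (alpha1 = 0, iota1 = 0, beta1 = 0) and eta = 1 unless heteroscedastic —
    and every value can be overridden from a configuration file.
    """

    scenario: str = "baseline"
    pi: float = 0.5
    alpha0: tuple[float, float] = (20.0, 170.0)
    alpha1: tuple[float, float] = (0.0, 0.0)
    Sigma: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 2.0), (2.0, 36.0))
    iota: tuple[float, float, float, float] = (-40.0, 0.0, 0.2, 0.6)
    lam: float = 1.0
    beta: tuple[float, float, float] = (0.5, 0.0, 0.01)
    theta: float = 0.02
    omega: float = 1.0
    eta: float = 1.0
    sigma_w: float = 8.0
    sigma_l: float = 0.3
    error_dist: str = "normal"
    lognormal_sigma: float = 0.25
    n: int = 1000
    missing_prob: float = 0.6
    missing_subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ANTHRO_SCENARIOS:
            raise SpecError(f"unknown scenario {self.scenario!r}")
        if self.error_dist not in ("normal", "lognormal"):
            raise SpecError(f"unknown error_dist {self.error_dist!r}")
        if self.error_dist == "lognormal" and self.scenario != "non_normal":
            raise SpecError("log-normal errors belong to the non_normal scenario only")
        if self.eta != 1.0 and self.scenario != "heteroscedastic":
            raise SpecError("eta != 1 belongs to the heteroscedastic scenario only")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise SpecError("missing_prob must lie in [0, 1]")
        if np.linalg.eigvalsh(np.asarray(self.Sigma)).min() <= 0:
            raise SpecError("Sigma must be positive definite")

    @classmethod
    def preset(cls, scenario: str, **overrides) -> "AnthroScenario":
        """Scenario with its defining switches applied."""
        implied: dict = {"scenario": scenario}
        if scenario == "heteroscedastic":
            implied["eta"] = 2.0
        elif scenario == "non_normal":
            implied["error_dist"] = "lognormal"
        elif scenario == "subgroup":
            implied["missing_subgroup"] = "sex"
        implied.update(overrides)
        return cls(**implied)

    def _errors(self, rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
        if self.error_dist == "normal":
            return scale * rng.standard_normal(size)
        s = self.lognormal_sigma
        raw = np.exp(rng.standard_normal(size) * s)
        mean = math.exp(s ** 2 / 2)
        sd = math.sqrt((math.exp(s ** 2) - 1) * math.exp(s ** 2))
        return scale * (raw - mean) / sd

    def generate(self, rng=None) -> Dataset:
        rng = as_generator(rng)
        n = self.n
        sex = (rng.random(n) < self.pi).astype(float)
        L = np.linalg.cholesky(np.asarray(self.Sigma, dtype=float))
        e = rng.standard_normal((n, 2)) @ L.T
        age = self.alpha0[0] + self.alpha1[0] * sex + e[:, 0]
        height = self.alpha0[1] + self.alpha1[1] * sex + e[:, 1]
        eta_sex = np.where(sex == 1.0, self.eta, 1.0)
        i0, i1, i2, i3 = self.iota
        weight = (i0 + i1 * sex + i2 * age + i3 * height
                  + eta_sex ** self.lam * self._errors(rng, n, self.sigma_w))
        b0, b1, b2 = self.beta
        loginsindex = (b0 + b1 * sex + b2 * age + self.theta * weight
                       + eta_sex ** self.omega * self._errors(rng, n, self.sigma_l))
        # MCAR on weight, optionally restricted to the sex = 1 subgroup
        drop = rng.random(n) < self.missing_prob
        if self.missing_subgroup is not None:
            if self.missing_subgroup != "sex":
                raise SpecError("missing_subgroup must name the binary 'sex' column")
            drop &= sex == 1.0
        weight = np.where(drop, np.nan, weight)
        return Dataset(pd.DataFrame({
            "sex": sex, "age": age, "height": height,
            "weight": weight, "loginsindex": loginsindex,
        }))

    def imputation_spec(self, M: int = 5) -> ImputationSpec:
        if self.scenario == "subgroup":
            # the uncongenial imputer pools the sexes, ignoring sex
            predictors = ("age", "height", "loginsindex")
        else:
            predictors = ("sex", "age", "height", "loginsindex")
        return ImputationSpec("weight", predictors, "mar_normal", M=M)

    def analysis_spec(self) -> AnalysisSpec:
        if self.scenario == "subgroup":
            return AnalysisSpec("loginsindex", ("weight", "age"), target="weight",
                                subgroup=("sex", 1.0))
        if self.scenario == "omitted_interaction":
            return AnalysisSpec("loginsindex", ("weight", "age", "sex"), target="weight",
                                interactions=(("weight", "sex"),))
        return AnalysisSpec("loginsindex", ("weight", "age", "sex"), target="weight")

    def true_target(self) -> float:
        return self.theta


def generate_trial_dataset(scenario: TrialScenario, rng=None) -> Dataset:
    return scenario.generate(rng)


def generate_anthro_dataset(scenario: AnthroScenario, rng=None) -> Dataset:
    return scenario.generate(rng)


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSummary:
    """Per-method summary of a coverage study."""

    method: str
    M: int
    B: int | None
    coverage_pct: float
    median_ci_width: float
    n_reps: int
    mc_se_pct: float
    n_failed: int = 0


@dataclass
class StudyResult:
    summaries: list[SimulationSummary]
    records: pd.DataFrame = field(repr=False)
    truth: float = float("nan")


RECORD_COLUMNS = ["rep", "method", "estimate", "variance", "df",
                  "ci_lower", "ci_upper", "covered", "width"]


def _run_reps(scenario, methods: Sequence[MethodSetting], rep_ids, seeds,
              truth: float, progress: Callable[[int], None] | None = None) -> list[dict]:
    rows = []
    for rep, seed in zip(rep_ids, seeds):
        streams = seed.spawn(len(methods) + 1)
        data = scenario.generate(np.random.default_rng(streams[0]))
        for j, setting in enumerate(methods):
            imp = scenario.imputation_spec(setting.M)
            ana = scenario.analysis_spec()
            rng = np.random.default_rng(streams[j + 1])
            try:
                res = run_method(data, imp, ana, setting, rng)
            except BootmiError:
                rows.append({"rep": rep, "method": setting.key, "estimate": np.nan,
                             "variance": np.nan, "df": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan, "covered": np.nan, "width": np.nan})
                continue
            rows.append({"rep": rep, "method": setting.key, "estimate": res.estimate,
                         "variance": res.variance, "df": res.df,
                         "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                         "covered": float(res.covers(truth)), "width": res.width})
        if progress is not None:
            progress(rep)
    return rows


def summarise(records: pd.DataFrame, methods: Sequence[MethodSetting]) -> list[SimulationSummary]:
    """Coverage (%), median interval width and MC SE per method."""
    out = []
    for setting in methods:
        sub = records[records["method"] == setting.key]
        ok = sub.dropna(subset=["covered"])
        n_ok = len(ok)
        out.append(SimulationSummary(
            method=setting.key, M=setting.M, B=setting.B,
            coverage_pct=100.0 * float(ok["covered"].mean()) if n_ok else float("nan"),
            median_ci_width=float(ok["width"].median()) if n_ok else float("nan"),
            n_reps=n_ok,
            mc_se_pct=mc_se(1.0 - setting.alpha, n_ok) if n_ok else float("nan"),
            n_failed=len(sub) - n_ok,
        ))
    return out


def run_study(scenario, methods: Sequence[MethodSetting], n_reps: int,
              master_seed, workers: int = 1,
              progress: Callable[[int], None] | None = None) -> StudyResult:
    """Replicate generate -> impute -> analyse -> pool for every method.

    Every method sees the identical simulated dataset within a replication;
    ``master_seed`` (an int or a :class:`numpy.random.SeedSequence`) makes
    the whole study reproducible, independently of ``workers``.
    """
    if n_reps < 1:
        raise SpecError("n_reps must be >= 1")
    keys = [m.key for m in methods]
    if len(set(keys)) != len(keys):
        raise SpecError("duplicate method settings")
    root = (master_seed if isinstance(master_seed, np.random.SeedSequence)
            else np.random.SeedSequence(master_seed))
    seeds = root.spawn(n_reps)
    truth = scenario.true_target()
    if workers > 1:
        from joblib import Parallel, delayed
        blocks = np.array_split(np.arange(n_reps), workers * 4)
        chunks = Parallel(n_jobs=workers)(
            delayed(_run_reps)(scenario, list(methods), block.tolist(),
                               [seeds[i] for i in block], truth)
            for block in blocks if len(block))
        rows = [row for chunk in chunks for row in chunk]
    else:
        rows = _run_reps(scenario, list(methods), range(n_reps), seeds, truth, progress)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return StudyResult(summarise(records, methods), records, truth)
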