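"""YAML configuration for the command-line interface.

Two modes are described by a config file:

``analyse``
    Read an incomplete CSV table, run one inference method, write a one-row
    report.

``simulate``
    Run a coverage study for a built-in scenario and write per-replication
    records plus a summary table.

Every key can be overridden by a CLI flag; flags win over the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .analysis import AnalysisSpec
from .data import DEFAULT_MISSING_TOKEN
from .exceptions import ConfigError, SpecError
from .imputation import ImputationSpec
from .methods import MethodSetting
from .simulate import AnthroScenario, TrialScenario


def load_yaml(path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping of keys to values")
    return cfg


def _require(mapping: dict, keys, context: str) -> None:
    missing = [k for k in keys if k not in mapping or mapping[k] is None]
    if missing:
        raise ConfigError(f"{context}: missing required keys {missing}")


def _imputation_spec(cfg: dict, M: int) -> ImputationSpec:
    _require(cfg, ["outcome", "predictors"], "imputation")
    try:
        return ImputationSpec(
            outcome=cfg["outcome"],
            predictors=tuple(cfg["predictors"]),
            method=cfg.get("method", "mar_normal"),
            treatment_column=cfg.get("treatment_column"),
            M=M,
        )
    except SpecError as exc:
        raise ConfigError(f"imputation: {exc}") from exc


def _analysis_spec(cfg: dict) -> AnalysisSpec:
    _require(cfg, ["outcome", "covariates", "target"], "analysis")
    subgroup = cfg.get("subgroup")
    if subgroup is not None:
        if not (isinstance(subgroup, (list, tuple)) and len(subgroup) == 2):
            raise ConfigError("analysis.subgroup must be a [column, value] pair")
        subgroup = (subgroup[0], float(subgroup[1]))
    interactions = tuple(tuple(p) for p in cfg.get("interactions", ()) or ())
    try:
        return AnalysisSpec(cfg["outcome"], tuple(cfg["covariates"]), cfg["target"],
                            subgroup=subgroup, interactions=interactions)
    except SpecError as exc:
        raise ConfigError(f"analysis: {exc}") from exc


def _method_setting(cfg: dict) -> MethodSetting:
    _require(cfg, ["name", "M"], "method")
    try:
        return MethodSetting(cfg["name"], int(cfg["M"]),
                             B=None if cfg.get("B") is None else int(cfg["B"]),
                             alpha=float(cfg.get("alpha", 0.05)),
                             df_method=cfg.get("df_method", "rubin"))
    except SpecError as exc:
        raise ConfigError(f"method: {exc}") from exc


@dataclass
class AnalyseRun:
    input: str
    output: str
    imputation: ImputationSpec
    analysis: AnalysisSpec
    method: MethodSetting
    seed: int
    missing_token: str = DEFAULT_MISSING_TOKEN


def build_analyse(cfg: dict) -> AnalyseRun:
    _require(cfg, ["input", "output", "imputation", "analysis", "method", "seed"], "analyse")
    method = _method_setting(cfg["method"])
    return AnalyseRun(
        input=str(cfg["input"]),
        output=str(cfg["output"]),
        imputation=_imputation_spec(cfg["imputation"], method.M),
        analysis=_analysis_spec(cfg["analysis"]),
        method=method,
        seed=int(cfg["seed"]),
        missing_token=str(cfg.get("missing_token", DEFAULT_MISSING_TOKEN)),
    )


def default_anthro_parameters() -> dict:
    """The bundled, editable parameter file for the anthropometric model."""
    with resources.files("bootmi.configs").joinpath("anthro_default.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_scenario(cfg: dict):
    _require(cfg, ["kind"], "scenario")
    kind = cfg["kind"]
    params = {k: v for k, v in cfg.items() if k != "kind"}
    try:
        if kind == "trial":
            return TrialScenario(**params)
        if kind == "anthro":
            base = default_anthro_parameters()
            name = params.pop("scenario", base.pop("scenario", "baseline"))
            merged = {**base, **params}
            merged = _coerce_anthro(merged)
            return AnthroScenario.preset(name, **merged)
    except (SpecError, TypeError) as exc:
        raise ConfigError(f"scenario: {exc}") from exc
    raise ConfigError(f"scenario: unknown kind {kind!r} (expected 'trial' or 'anthro')")


def _coerce_anthro(params: dict) -> dict:
    out = dict(params)
    for key in ("alpha0", "alpha1", "iota", "beta"):
        if key in out:
            out[key] = tuple(float(v) for v in out[key])
    if "Sigma" in out:
        out["Sigma"] = tuple(tuple(float(v) for v in row) for row in out["Sigma"])
    return out


@dataclass
class SimulateRun:
    scenario: object
    methods: list[MethodSetting]
    n_reps: int
    seed: int
    out_records: str
    out_summary: str
    workers: int = 1
    grids: dict = field(default_factory=dict)


def build_simulate(cfg: dict) -> SimulateRun:
    _require(cfg, ["scenario", "methods", "n_reps", "seed", "out_records", "out_summary"],
             "simulate")
    methods = [_method_setting(m) for m in cfg["methods"]]
    if not methods:
        raise ConfigError("simulate: at least one method is required")
    return SimulateRun(
        scenario=build_scenario(cfg["scenario"]),
        methods=methods,
        n_reps=int(cfg["n_reps"]),
        seed=int(cfg["seed"]),
        out_records=str(cfg["out_records"]),
        out_summary=str(cfg["out_summary"]),
        workers=int(cfg.get("workers", 1)),
    )
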