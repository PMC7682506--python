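# bootmi

Confidence intervals for analyses of multiply imputed data — Rubin's rules
and the bootstrap/MI combinations that remain valid when they do not.

## Why

Multiple imputation (MI) fills missing values M times from a Bayesian
predictive model; the analysis model is fitted to each completed dataset and
the results pooled with Rubin's rules: point estimate θ̄_M = M⁻¹Σθ̂_m and
total variance

    T = W̄_M + (1 + 1/M)·B_M,   B_M = (M−1)⁻¹ Σ (θ̂_m − θ̄_M)².

Those rules are frequentist-valid only when the imputation model and the
analyst's procedure are *congenial* (a single Bayesian model embeds both)
and correctly specified. In routine practice they often are not — the
imputer uses variables or assumptions the analyst does not (reference-based
"jump to reference" imputation in trials, imputing a pooled sample for a
subgroup analysis), or both models are misspecified (heteroscedastic,
non-normal errors). Then T can be badly biased in either direction and
intervals over- or under-cover.

`bootmi` implements, with one consistent interface, the combinations of
bootstrapping and MI that have been proposed to deal with this, for scalar
OLS targets:

| method key           | construction                                             | valid under uncongeniality? |
|----------------------|----------------------------------------------------------|------|
| `rubin`              | Rubin's rules, model-based within variance                | no   |
| `mi_boot_rubin`      | Rubin's rules, bootstrap within variance                  | no   |
| `mi_boot_pooled`     | percentiles of the pooled M·B impute-then-boot estimates  | no (and under-covers at small M) |
| `boot_mi_percentile` | percentiles of per-resample means, boot-then-impute       | yes (M moderate; M = 1 over-covers) |
| `boot_mi_vonhippel`  | one-way ANOVA variance components on the boot-then-impute grid, Satterthwaite-df t interval | yes, and ~5× cheaper |

The von Hippel interval treats the bootstrap-then-MI grid θ̂_bm as a one-way
random-effects model and estimates Var(θ̄_BM) = ((B+1)/(BM))·MSB − MSW/M.
It is the recommended method when uncongeniality or misspecification is a
concern. See `docs/methods.md` for the full formulas, conventions and
design decisions.

Also included: proper Bayesian normal-regression imputation under MAR,
single-timepoint jump-to-reference imputation, and a simulation engine that
measures repeated-sampling coverage and interval width of all five methods
under congenial, uncongenial and misspecified designs.

## Worked example

Simulate one two-arm trial (n = 500, treatment effect 0.2 on Y, Y missing
completely at random for half the subjects), impute by jump to reference,
and compare Rubin's rules with the von Hippel interval:

```python
import numpy as np
from bootmi import (AnalysisSpec, ImputationSpec, MethodSetting,
                    TrialScenario, boot_mi_estimates, run_method,
                    von_hippel_inference)

scenario = TrialScenario(imputation_method="jump_to_reference")
data = scenario.generate(np.random.default_rng(42))

imp = ImputationSpec("y", ("x",), "jump_to_reference", treatment_column="z")
ana = AnalysisSpec("y", ("x", "z"), target="z")

rubin = run_method(data, imp, ana, MethodSetting("rubin", M=10), rng=1)
grid = boot_mi_estimates(data, imp, ana, B=1000, M=2, rng=2)
vh = von_hippel_inference(grid)

for r in (rubin, vh):
    print(f"{r.method:18s} estimate={r.estimate:.3f} "
          f"95% CI=({r.ci_lower:.3f}, {r.ci_upper:.3f}) "
          f"width={r.width:.3f} df={r.df:.1f}")
```

```
rubin              estimate=0.156 95% CI=(0.036, 0.275) width=0.239 df=83.2
boot_mi_vonhippel  estimate=0.138 95% CI=(0.065, 0.211) width=0.146 df=464.8
```

Both point estimates sit near 0.1 — the J2R estimand here is
(1 − 0.5)×0.2 = 0.1, because imputed active-arm outcomes revert to control
behaviour. The Rubin interval is ~60% wider: the reference-based imputer
assumes more than the analyst, which biases Rubin's variance upwards
(over-coverage ≈ 99.8% across repeated samples), while the von Hippel
interval keeps its nominal 95%.

The same grid can be released to analysts in clustered form
(`grid.to_csv("draws.csv")`, columns `b`, `m`, `estimate`) and pooled
externally.

## Command line

```bash
bootmi analyse  --config analyse.yaml    # dataset in, one-row report out
bootmi simulate --config simulate.yaml   # coverage study, records + summary CSVs
```

Config files are plain YAML (keys mirror the library's `ImputationSpec`,
`AnalysisSpec`, `MethodSetting`, scenario dataclasses); flags override the
file. Exit codes: 0 success, 1 user error, 2 internal failure.

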