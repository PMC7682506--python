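import numpy as np
import pandas as pd
import pytest

from bootmi import (AnthroScenario, MethodSetting, SpecError, TrialScenario,
                    mc_se, run_study, summarise)


# -- Monte-Carlo standard error --------------------------------------------

def test_mc_se_reported_values():
    assert mc_se(0.95, 1000) == pytest.approx(0.689, abs=5e-4)
    assert round(mc_se(0.95, 1000), 2) == 0.69
    # the commonly quoted 0.43% figure at 10,000 replications is the 95%
    # Monte-Carlo margin 1.96 x SE, not the SE itself (which is 0.218%)
    assert mc_se(0.95, 10_000) == pytest.approx(0.218, abs=5e-4)
    assert round(1.96 * mc_se(0.95, 10_000), 2) == 0.43
    assert mc_se(0.5, 4) == pytest.approx(25.0, abs=1e-12)


# -- trial generator -------------------------------------------------------

def test_trial_exact_arm_counts(rng):
    d = TrialScenario().generate(rng)
    z = d.column("z")
    assert (z == 1.0).sum() == 250
    assert (z == 0.0).sum() == 250


def test_trial_no_missing_when_prob_zero(rng):
    d = TrialScenario(missing_prob=0.0).generate(rng)
    assert not d.missing_mask.any().any()


def test_trial_moments_at_large_n(rng):
    sc = TrialScenario(n=100_000, arm_size=50_000, missing_prob=0.0)
    d = sc.generate(rng)
    x, y, z = d.column("x"), d.column("y"), d.column("z")
    active = z == 1.0
    # mean of Y in the active arm is 2 + 0.2 within 3 MC SEs
    se_mean = np.sqrt(0.4 / active.sum())
    assert y[active].mean() == pytest.approx(2.2, abs=3 * se_mean)
    assert y[~active].mean() == pytest.approx(2.0, abs=3 * se_mean)
    # covariance of (X, Y) within an arm is 0.2
    cov = np.cov(x[active], y[active])[0, 1]
    se_cov = np.sqrt((0.4 * 0.4 + 0.2 ** 2) / active.sum())
    assert cov == pytest.approx(0.2, abs=3 * se_cov)
    assert x.var(ddof=1) == pytest.approx(0.4, rel=0.03)


def test_trial_missing_rate(rng):
    d = TrialScenario().generate(rng)
    frac = d.missing_mask["y"].mean()
    assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 500))


def test_trial_estimand_under_j2r():
    assert TrialScenario().true_target() == 0.2
    j2r = TrialScenario(imputation_method="jump_to_reference")
    assert j2r.true_target() == pytest.approx(0.1)
    assert TrialScenario(imputation_method="jump_to_reference",
                         missing_prob=0.3).true_target() == pytest.approx(0.14)


def test_trial_validation():
    with pytest.raises(SpecError):
        TrialScenario(n=500, arm_size=200)
    with pytest.raises(SpecError):
        TrialScenario(var_x=0.1, var_y=0.1, cov_xy=0.5)


# -- anthropometric generator ----------------------------------------------

def test_anthro_null_sex_effects_give_identical_distributions(rng):
    sc = AnthroScenario(n=100_000, missing_prob=0.0)
    d = sc.generate(rng)
    sex = d.column("sex")
    for col in ("age", "height", "weight", "loginsindex"):
        v = d.column(col)
        men, women = v[sex == 1.0], v[sex == 0.0]
        se = np.sqrt(men.var() / men.size + women.var() / women.size)
        assert men.mean() - women.mean() == pytest.approx(0.0, abs=4 * se)
        assert men.std() == pytest.approx(women.std(), rel=0.03)


def test_anthro_heteroscedastic_doubles_residual_sd(rng):
    sc = AnthroScenario.preset("heteroscedastic", n=100_000, missing_prob=0.0)
    d = sc.generate(rng)
    sex = d.column("sex")
    ratios = []
    for s in (0.0, 1.0):
        sub = d.frame[sex == s]
        X = np.column_stack([np.ones(len(sub)), sub["age"], sub["height"]])
        beta, *_ = np.linalg.lstsq(X, sub["weight"].to_numpy(), rcond=None)
        resid = sub["weight"].to_numpy() - X @ beta
        ratios.append(resid.std())
    assert ratios[1] / ratios[0] == pytest.approx(2.0, rel=0.03)


def test_anthro_missingness_rates(rng):
    d = AnthroScenario(n=20_000).generate(rng)
    assert d.missing_mask["weight"].mean() == pytest.approx(0.6, abs=0.02)
    sub = AnthroScenario.preset("subgroup", n=20_000).generate(rng)
    sex = sub.column("sex")
    miss = sub.missing_mask["weight"].to_numpy()
    assert miss[sex == 0.0].sum() == 0          # women fully observed
    assert miss[sex == 1.0].mean() == pytest.approx(0.6, abs=0.03)


def test_anthro_lognormal_errors_keep_scale_but_skew(rng):
    sc = AnthroScenario.preset("non_normal", n=100_000, missing_prob=0.0)
    d = sc.generate(rng)
    X = np.column_stack([np.ones(sc.n), d.column("sex"), d.column("age"),
                         d.column("height")])
    beta, *_ = np.linalg.lstsq(X, d.column("weight"), rcond=None)
    resid = d.column("weight") - X @ beta
    assert resid.std() == pytest.approx(sc.sigma_w, rel=0.02)
    from scipy import stats
    skew = stats.skew(resid)
    assert 0.4 < skew < 1.2  # log-normal sigma 0.25 has skewness ~0.78


def test_anthro_scenario_validation():
    with pytest.raises(SpecError):
        AnthroScenario(scenario="bogus")
    with pytest.raises(SpecError):
        AnthroScenario(eta=2.0)  # eta != 1 outside the heteroscedastic scenario
    with pytest.raises(SpecError):
        AnthroScenario(error_dist="lognormal")


# -- study runner ----------------------------------------------------------

def small_scenario():
    return TrialScenario(n=80, arm_size=40, missing_prob=0.3)


def test_run_study_reproducible():
    methods = [MethodSetting("rubin", M=3)]
    a = run_study(small_scenario(), methods, n_reps=4, master_seed=99)
    b = run_study(small_scenario(), methods, n_reps=4, master_seed=99)
    pd.testing.assert_frame_equal(a.records, b.records)
    assert a.summaries == b.summaries


def test_run_study_workers_match_serial():
    methods = [MethodSetting("rubin", M=3)]
    a = run_study(small_scenario(), methods, n_reps=6, master_seed=5, workers=1)
    b = run_study(small_scenario(), methods, n_reps=6, master_seed=5, workers=2)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_run_study_shares_datasets_across_methods():
    """Methods are compared on identical simulated data: the rubin estimates
    are unchanged by adding a second method to the list."""
    m1 = [MethodSetting("rubin", M=3)]
    m2 = [MethodSetting("rubin", M=3), MethodSetting("boot_mi_vonhippel", M=2, B=10)]
    a = run_study(small_scenario(), m1, n_reps=3, master_seed=17)
    b = run_study(small_scenario(), m2, n_reps=3, master_seed=17)
    ra = a.records[a.records.method == "rubin[M=3]"].reset_index(drop=True)
    rb = b.records[b.records.method == "rubin[M=3]"].reset_index(drop=True)
    pd.testing.assert_frame_equal(ra, rb)


def test_summarise_hand_built_records():
    setting = MethodSetting("rubin", M=2)
    rec = pd.DataFrame({
        "rep": [0, 1, 2], "method": [setting.key] * 3,
        "estimate": [0.1, 0.2, 0.3], "variance": [1.0] * 3, "df": [10.0] * 3,
        "ci_lower": [0.0] * 3, "ci_upper": [1.0] * 3,
        "covered": [1.0, 1.0, 1.0], "width": [1.0, 2.0, 3.0],
    })
    (s,) = summarise(rec, [setting])
    assert s.coverage_pct == 100.0
    assert s.median_ci_width == 2.0
    assert s.n_reps == 3
    assert s.mc_se_pct == pytest.approx(mc_se(0.95, 3))


def test_summarise_counts_failures():
    setting = MethodSetting("rubin", M=2)
    rec = pd.DataFrame({
        "rep": [0, 1], "method": [setting.key] * 2,
        "estimate": [0.1, np.nan], "variance": [1.0, np.nan], "df": [10.0, np.nan],
        "ci_lower": [0.0, np.nan], "ci_upper": [1.0, np.nan],
        "covered": [0.0, np.nan], "width": [1.0, np.nan],
    })
    (s,) = summarise(rec, [setting])
    assert s.n_failed == 1
    assert s.n_reps == 1
    assert s.coverage_pct == 0.0
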