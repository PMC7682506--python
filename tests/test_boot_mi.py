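import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bootmi import (AnalysisSpec, EstimateGrid, ImputationSpec,
                    MethodSetting, SpecError, anova_components,
                    boot_mi_estimates, boot_mi_percentile,
                    run_method, satterthwaite_df, von_hippel_inference,
                    von_hippel_variance)

ANA = AnalysisSpec("y", ("x", "z"), "z")
IMP = ImputationSpec("y", ("x", "z"), "mar_normal")


# -- ANOVA components ------------------------------------------------------

def test_anova_hand_example():
    vc = anova_components(np.array([[1.0, 1.0], [3.0, 3.0]]))
    assert vc.msb == pytest.approx(4.0, abs=1e-12)
    assert vc.msw == pytest.approx(0.0, abs=1e-12)
    assert vc.sigma2_inf == pytest.approx(2.0, abs=1e-12)
    assert vc.sigma2_btw == pytest.approx(0.0, abs=1e-12)
    assert not vc.fallback_used


def test_anova_fallback_branch():
    vc = anova_components(np.array([[1.0, 3.0], [2.0, 4.0]]))
    assert vc.msb == pytest.approx(1.0, abs=1e-12)
    assert vc.msw == pytest.approx(2.0, abs=1e-12)
    assert vc.fallback_used
    assert vc.sigma2_inf == 0.0
    assert vc.sigma2_btw == pytest.approx(5.0 / 3.0, abs=1e-12)


def test_anova_all_equal():
    vc = anova_components(np.full((3, 2), 7.0))
    assert vc.msb == vc.msw == vc.sigma2_inf == vc.sigma2_btw == 0.0


@given(st.integers(2, 6), st.integers(2, 5), st.integers(0, 2 ** 31 - 1))
def test_anova_matches_sum_of_squares_oracle(B, M, seed):
    vals = np.random.default_rng(seed).normal(size=(B, M))
    vc = anova_components(vals)
    grand = vals.mean()
    means = vals.mean(axis=1)
    msb = M * ((means - grand) ** 2).sum() / (B - 1)
    msw = sum((vals[b] - means[b]) @ (vals[b] - means[b]) for b in range(B)) / (B * (M - 1))
    assert vc.msb == pytest.approx(msb, rel=1e-10, abs=1e-12)
    assert vc.msw == pytest.approx(msw, rel=1e-10, abs=1e-12)


def test_anova_recovers_known_components(rng):
    """Parameter recovery on a synthetic two-level grid (B = 2000, M = 2)."""
    B, M = 2000, 2
    s_inf, s_btw = 1.0, 0.5
    vals = (rng.normal(0.0, np.sqrt(s_inf), size=(B, 1))
            + rng.normal(0.0, np.sqrt(s_btw), size=(B, M)))
    vc = anova_components(vals)
    assert vc.sigma2_inf == pytest.approx(s_inf, rel=0.10)
    assert vc.sigma2_btw == pytest.approx(s_btw, rel=0.10)


def test_anova_needs_replication():
    with pytest.raises(SpecError):
        anova_components(np.ones((5, 1)))
    with pytest.raises(SpecError):
        anova_components(np.ones((1, 3)))


# -- von Hippel variance and df --------------------------------------------

@given(st.floats(0.0, 100.0), st.floats(0.0, 100.0),
       st.integers(2, 5000), st.integers(2, 200))
def test_variance_forms_identical(msb, msw, B, M):
    """(1 + 1/B)(MSB - MSW)/M + MSW/(BM) == ((B+1)/(BM)) MSB - MSW/M."""
    a = (1 + 1 / B) * (msb - msw) / M + msw / (B * M)
    b = von_hippel_variance(msb, msw, B, M)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


@given(st.floats(0.01, 50.0), st.integers(2, 500), st.integers(2, 20))
def test_df_is_b_minus_1_when_msw_zero(msb, B, M):
    assert satterthwaite_df(msb, 0.0, B, M) == B - 1


def test_von_hippel_hand_example():
    res = von_hippel_inference(np.array([[1.0, 1.0], [3.0, 3.0]]))
    assert res.estimate == pytest.approx(2.0, abs=1e-12)
    assert res.variance == pytest.approx(3.0, abs=1e-12)
    assert res.df == pytest.approx(1.0, abs=1e-12)
    half = stats.t.ppf(0.975, 1) * np.sqrt(3.0)
    assert res.ci_upper == pytest.approx(2.0 + half, rel=1e-10)
    assert stats.t.ppf(0.975, 1) == pytest.approx(12.706, abs=5e-4)


def test_von_hippel_fallback_variance():
    # fallback: variance = s2_tot / (BM) = (5/3)/4
    res = von_hippel_inference(np.array([[1.0, 3.0], [2.0, 4.0]]))
    assert res.variance == pytest.approx(5.0 / 12.0, abs=1e-12)
    assert res.estimate == pytest.approx(2.5, abs=1e-12)


def test_von_hippel_degenerate_grid():
    res = von_hippel_inference(np.full((4, 2), 1.5))
    assert res.variance == 0.0
    assert res.ci_lower == res.ci_upper == 1.5


def test_variance_never_negative(rng):
    for _ in range(200):
        vals = rng.normal(size=(3, 2))
        assert von_hippel_inference(vals).variance >= 0.0


def test_variance_of_grand_mean_formula(rng):
    """Direct simulation of theta_bm = c_b + d_bm: the repeated-sampling
    variance of the grand mean matches (1 + 1/B) s_inf + s_btw/(BM)."""
    B, M, s_inf, s_btw = 30, 2, 1.0, 0.8
    reps = 4000
    # the full-data estimate itself varies across repeated samples with
    # variance s_inf; bootstrap deviations c_b vary around it with the same
    # variance, and d_bm adds imputation noise
    theta_inf = rng.normal(0.0, np.sqrt(s_inf), size=(reps, 1, 1))
    c = rng.normal(0.0, np.sqrt(s_inf), size=(reps, B, 1))
    d = rng.normal(0.0, np.sqrt(s_btw), size=(reps, B, M))
    grand = (theta_inf + c + d).mean(axis=(1, 2))
    expected = (1 + 1 / B) * s_inf + s_btw / (B * M)
    assert grand.var(ddof=1) == pytest.approx(expected, rel=0.10)


# -- percentile interval ---------------------------------------------------

def test_percentile_hand_example():
    """Per-replicate means (1..5): with total error rate 0.4 the endpoints
    are the 20% and 80% linearly interpolated percentiles."""
    grid = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
    res = boot_mi_percentile(grid, alpha=0.4)
    assert res.ci_lower == pytest.approx(1.8, abs=1e-12)
    assert res.ci_upper == pytest.approx(4.2, abs=1e-12)
    assert res.estimate == pytest.approx(3.0, abs=1e-12)


def test_percentile_constant_grid():
    res = boot_mi_percentile(np.full((6, 2), 2.5))
    assert res.ci_lower == res.ci_upper == 2.5


def test_percentile_permutation_invariant(rng):
    vals = rng.normal(size=(40, 3))
    a = boot_mi_percentile(vals)
    b = boot_mi_percentile(vals[rng.permutation(40)])
    assert a.ci_lower == pytest.approx(b.ci_lower, abs=1e-12)
    assert a.ci_upper == pytest.approx(b.ci_upper, abs=1e-12)


# -- the grid builder ------------------------------------------------------

def test_complete_data_gives_zero_within_variance(linear_data):
    """No missingness: the M imputations of each resample are identical, so
    MSW = 0 exactly."""
    grid = boot_mi_estimates(linear_data, ImputationSpec("y", ("x", "g")),
                             AnalysisSpec("y", ("x", "g"), "x"), B=20, M=2, rng=3)
    vc = anova_components(grid)
    assert vc.msw == 0.0
    assert satterthwaite_df(vc.msb, vc.msw, grid.B, grid.M) == grid.B - 1


def test_grid_deterministic(incomplete_trial):
    a = boot_mi_estimates(incomplete_trial, IMP, ANA, B=15, M=2, rng=8)
    b = boot_mi_estimates(incomplete_trial, IMP, ANA, B=15, M=2, rng=8)
    np.testing.assert_array_equal(a.values, b.values)


def test_grid_mean_near_mi_estimate(incomplete_trial):
    """Bootstrap consistency: the grid mean approaches the MI point estimate
    on the original data as B grows."""
    grid = boot_mi_estimates(incomplete_trial, IMP, ANA, B=2000, M=2, rng=13)
    mi_est = run_method(incomplete_trial, IMP, ANA,
                        MethodSetting("rubin", M=200), rng=14).estimate
    assert grid.values.mean() == pytest.approx(mi_est, abs=0.02)


def test_grid_release_can_be_pooled_externally(incomplete_trial, tmp_path):
    """The clustered (b, m, estimate) release format round-trips and feeds
    the pooling functions unchanged."""
    grid = boot_mi_estimates(incomplete_trial, IMP, ANA, B=25, M=2, rng=4)
    path = tmp_path / "grid.csv"
    grid.to_csv(path)
    back = EstimateGrid.from_csv(path)
    a, b = von_hippel_inference(grid), von_hippel_inference(back)
    assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
    assert a.variance == pytest.approx(b.variance, rel=1e-12)
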