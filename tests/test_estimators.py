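"""Point estimators, confidence intervals, and the bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rctadjust.core import TrialDataset
from rctadjust.estimators import (
    _hajek_theta,
    ancova_estimate,
    bootstrap_se,
    confidence_interval,
    estimate_iptw,
    unadjusted_estimate,
)
from rctadjust.exceptions import ConfigurationError, EstimationError
from conftest import make_trial


# -- ANCOVA / unadjusted ------------------------------------------------------


def test_unadjusted_is_difference_of_arm_means(small_trial):
    est = unadjusted_estimate(small_trial)
    y, z = small_trial.outcome, small_trial.treatment
    assert est.theta_hat == pytest.approx(y[z == 1].mean() - y[z == 0].mean(), rel=1e-12)
    assert est.method == "unadjusted" and est.residual_df == small_trial.n - 2


def test_equal_arms_equal_means():
    y = np.array([10.0, 5.0, 10.0, 5.0, 10.0, 5.0, 10.0, 5.0])
    z = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    data = TrialDataset(np.arange(8).astype(str), z, y,
                        np.empty((8, 0)), ())
    est = unadjusted_estimate(data)
    assert est.theta_hat == pytest.approx(0.0)
    assert est.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("subset", [(), ("C1",), ("C1", "C2", "C3")])
def test_ancova_matches_statsmodels(seed, subset):
    """theta, SE, CI and p agree with an independently fitted OLS."""
    import statsmodels.api as sm

    data = make_trial(n=35, p=3, seed=seed)
    est = ancova_estimate(data, subset) if subset else unadjusted_estimate(data)
    X = sm.add_constant(
        np.column_stack([data.treatment, data.covariate_matrix(subset)])
        if subset
        else data.treatment.astype(float)
    )
    ref = sm.OLS(data.outcome, X).fit()
    assert est.theta_hat == pytest.approx(ref.params[1], rel=1e-10)
    assert est.se_hat == pytest.approx(ref.bse[1], rel=1e-10)
    assert est.p_value == pytest.approx(ref.pvalues[1], rel=1e-8)
    lo, hi = ref.conf_int()[1]
    assert est.ci_low == pytest.approx(lo, rel=1e-8)
    assert est.ci_high == pytest.approx(hi, rel=1e-8)


def test_covariate_orthogonal_to_treatment_leaves_theta_unchanged():
    data = make_trial(n=40, p=1, seed=4)
    z = data.treatment
    x = np.random.default_rng(8).standard_normal(data.n)
    x[z == 1] -= x[z == 1].mean()  # mean 0 within each arm -> orthogonal to 1 and z
    x[z == 0] -= x[z == 0].mean()
    ortho = TrialDataset(data.subject_id, z, data.outcome, x.reshape(-1, 1), ("o",))
    assert ancova_estimate(ortho, ("o",)).theta_hat == pytest.approx(
        unadjusted_estimate(ortho).theta_hat, abs=1e-10
    )


def test_rank_deficient_design_raises():
    data = make_trial(n=20, p=1, seed=0)
    x = data.covariates[:, :1]
    clone = TrialDataset(data.subject_id, data.treatment, data.outcome,
                         np.column_stack([x, x]), ("a", "b"))
    with pytest.raises(EstimationError):
        ancova_estimate(clone, ("a", "b"))


# -- IPTW ---------------------------------------------------------------------


def test_hajek_toy_hand_computed(toy_dataset):
    """Weighted mean difference on the 6-subject toy with fixed scores."""
    ps = toy_dataset.covariates[:, 0]  # {.5,.8 | .5,.5,.2,.2}
    z = toy_dataset.treatment
    w = np.where(z == 1, 1 / ps, 1 / (1 - ps))
    # by hand: mu1 = (2*10 + 1.25*12)/3.25, mu0 = (2*5 + 2*6 + 1.25*7 + 1.25*8)/6.5
    mu1 = (2 * 10 + 1.25 * 12) / 3.25
    mu0 = (2 * 5 + 2 * 6 + 1.25 * 7 + 1.25 * 8) / 6.5
    assert _hajek_theta(toy_dataset.outcome, z, w) == pytest.approx(mu1 - mu0, rel=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.sampled_from([20, 41, 60]))
def test_hajek_equals_wls_slope(seed, n):
    """The Hajek difference equals the WLS slope of outcome on treatment."""
    data = make_trial(n=n, p=2, seed=seed)
    rng = np.random.default_rng(seed + 1)
    w = rng.uniform(1.0, 5.0, size=n)
    y, z = data.outcome, data.treatment.astype(float)
    X = np.column_stack([np.ones(n), z])
    beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
    assert _hajek_theta(y, data.treatment, w) == pytest.approx(beta[1], abs=1e-10)


def test_constant_weights_collapse_to_unadjusted():
    """Equal arms + intercept-only score -> IPTW equals the mean difference."""
    data = make_trial(n=40, p=1, seed=12)
    # force exactly equal arms
    z = np.array([0, 1] * 20)
    eq = TrialDataset(data.subject_id, z, data.outcome, data.covariates, data.covariate_names)
    est = estimate_iptw(eq, ())
    assert est.theta_hat == pytest.approx(unadjusted_estimate(eq).theta_hat, abs=1e-10)


def test_iptw_estimate_metadata(small_trial):
    est = estimate_iptw(small_trial, ("C1", "C2"))
    assert est.method == "iptw" and est.reference_distribution == "normal"
    assert est.adjusted_covariates == ("C1", "C2")
    assert est.ci_low < est.theta_hat < est.ci_high
    assert est.extra["propensity_fit"].converged


# -- confidence intervals -----------------------------------------------------


def test_normal_interval_quantile():
    lo, hi, p = confidence_interval(0.0, 1.0, "normal")
    assert lo == pytest.approx(-1.959964, abs=1e-6)
    assert hi == pytest.approx(1.959964, abs=1e-6)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("df", [3, 10, 58])
def test_t_interval_wider_than_normal(df):
    n_lo, n_hi, _ = confidence_interval(5.0, 1.0, "normal")
    t_lo, t_hi, _ = confidence_interval(5.0, 1.0, "t", residual_df=df)
    assert t_lo < n_lo and t_hi > n_hi


@pytest.mark.parametrize("ref,df", [("normal", None), ("t", 17)])
@pytest.mark.parametrize("level", [0.8, 0.95, 0.99])
def test_p_value_at_ci_boundary(ref, df, level):
    """An estimate sitting exactly on the CI boundary has p = 1 - level."""
    _, hi, _ = confidence_interval(0.0, 2.0, ref, residual_df=df, level=level)
    _, _, p = confidence_interval(hi, 2.0, ref, residual_df=df, level=level)
    assert p == pytest.approx(1.0 - level, abs=1e-10)


def test_ci_configuration_errors():
    with pytest.raises(ConfigurationError):
        confidence_interval(0.0, 1.0, "t")  # df missing
    with pytest.raises(ConfigurationError):
        confidence_interval(0.0, -1.0, "normal")
    with pytest.raises(ConfigurationError):
        confidence_interval(0.0, 1.0, "normal", level=1.5)


# -- bootstrap ----------------------------------------------------------------


def test_bootstrap_constant_outcome_gives_zero_se():
    data = make_trial(n=30, p=1, seed=1)
    const = TrialDataset(data.subject_id, data.treatment, np.full(30, 7.0),
                         data.covariates, data.covariate_names)
    se, _ = bootstrap_se(const, "unadjusted", n_boot=200, seed=0)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_tracks_analytic_se_of_mean_difference():
    """Unadjusted bootstrap SE vs the closed-form SE on a fixed n=200 trial."""
    data = make_trial(n=200, p=1, seed=21)
    se, _ = bootstrap_se(data, "unadjusted", n_boot=10_000, seed=5)
    y, z = data.outcome, data.treatment
    y1, y0 = y[z == 1], y[z == 0]
    analytic = np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0))
    assert se == pytest.approx(analytic, rel=0.05)


def test_bootstrap_is_seed_deterministic(small_trial):
    a, _ = bootstrap_se(small_trial, "iptw", ("C1",), n_boot=50, seed=3)
    b, _ = bootstrap_se(small_trial, "iptw", ("C1",), n_boot=50, seed=3)
    assert a == b


def test_bootstrap_unstable_raises():
    data = make_trial(n=30, p=1, seed=5)
    sep = TrialDataset(data.subject_id, data.treatment, data.outcome,
                       data.treatment.astype(float).reshape(-1, 1), ("d",))
    with pytest.raises(EstimationError, match="unstable"):
        bootstrap_se(sep, "iptw", ("d",), n_boot=50, seed=0)


def test_bootstrap_rejects_bad_arguments(small_trial):
    with pytest.raises(ConfigurationError):
        bootstrap_se(small_trial, "unadjusted", n_boot=1)
    with pytest.raises(ConfigurationError):
        bootstrap_se(small_trial, "ipw-typo")
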