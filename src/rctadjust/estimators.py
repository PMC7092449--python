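"""Treatment-effect estimators for two-arm trials with a continuous outcome.

Three estimators of the (marginal) treatment effect theta:

``unadjusted``
    OLS of outcome on treatment only; theta is the difference in arm means.
``regression`` (ANCOVA)
    OLS of outcome on treatment plus baseline covariates; model-based SE,
    t-based CI with ``n - (p + 2)`` residual degrees of freedom.
``iptw``
    Inverse-probability-of-treatment weighting with the propensity score
    e(X) = P(Z=1 | X) estimated by logistic regression even though the
    design guarantees e = 1/2 — re-estimating the score is what buys the
    precision gain.  Each participant is weighted by the reciprocal of the
    probability of the arm actually received (w = 1/e for treated,
    1/(1-e) for controls, never truncated), theta is the Hajek
    (ratio-normalised) weighted mean difference — identical to the slope
    of a weighted least-squares fit of outcome on treatment — and the SE
    comes from the full M-estimation sandwich that stacks the weighted
    moment conditions with the logistic score equations, so the sampling
    uncertainty of the estimated propensity score is propagated.  CIs are
    normal-based.

The sandwich is the point of the exercise: treating the estimated score as
known gives a strictly larger variance on the same data, and at large n the
full-sandwich SE converges to the ANCOVA model-based SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from functools import lru_cache

from scipy import special

from .core import AdjustedEstimate, TrialDataset
from .exceptions import ConfigurationError, EstimationError

__all__ = [
    "PropensityFit",
    "IPTWWeights",
    "fit_propensity_logistic",
    "compute_iptw_weights",
    "estimate_iptw",
    "sandwich_variance_iptw",
    "ancova_estimate",
    "unadjusted_estimate",
    "bootstrap_se",
    "confidence_interval",
]

#: IRLS stops when every score component is below this.
SCORE_TOL = 1e-8
#: IRLS iteration cap.
MAX_ITER = 50
#: |coefficient| beyond this flags separation: under randomization the true
#: log-odds are 0, so a huge coefficient means the MLE is diverging.
SEPARATION_BOUND = 20.0


@dataclass(frozen=True)
class PropensityFit:
    """A fitted logistic propensity model.

    ``alpha_hat`` holds the coefficients, intercept first; ``ps`` the fitted
    scores expit(x' alpha), all strictly inside (0, 1).  ``converged`` is
    False on non-convergence or suspected separation — callers must check
    it before weighting.
    """

    alpha_hat: np.ndarray
    ps: np.ndarray
    converged: bool
    n_iterations: int
    covariate_names: tuple[str, ...]


@dataclass(frozen=True)
class IPTWWeights:
    """Inverse-probability weights, one per participant, all finite and > 1."""

    w: np.ndarray


# -- array-level cores (hot path of the Monte-Carlo engine) -------------------


def _logit_irls(X: np.ndarray, z: np.ndarray):
    """Newton/IRLS MLE of the Bernoulli log-likelihood.

    Returns ``(alpha, ps, converged, n_iter)``.  Raises EstimationError on a
    rank-deficient design; flags (does not raise) non-convergence and
    separation.
    """
    n, d = X.shape
    if np.linalg.matrix_rank(X) < d:
        raise EstimationError(
            f"propensity design matrix is rank deficient ({d} columns, rank < {d})"
        )
    alpha = np.zeros(d)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ alpha
        ps = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (z - ps)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = ps * (1.0 - ps)
        # Fisher information X' W X; fall back to flagged failure if singular
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            converged = False
            break
        alpha = alpha + step
        if np.max(np.abs(alpha)) > SEPARATION_BOUND:
            converged = False
            break
    eta = X @ alpha
    ps = 1.0 / (1.0 + np.exp(-eta))
    if np.max(np.abs(alpha)) > SEPARATION_BOUND:
        converged = False
    # clip only pathological exact 0/1 from overflow; flagged non-converged anyway
    eps = np.finfo(float).tiny
    ps = np.clip(ps, eps, 1.0 - eps)
    return alpha, ps, converged, it


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via normal equations: ``(beta, cov_beta, df)`` with the usual
    model-based covariance ``sigma2 * (X'X)^{-1}``, ``sigma2 = RSS/df``."""
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise EstimationError(f"non-positive residual df: n={n}, parameters={k}")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise EstimationError("design matrix is singular (rank deficient)") from None
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    return beta, sigma2 * xtx_inv, df


def _hajek_theta(y: np.ndarray, z: np.ndarray, w: np.ndarray) -> float:
    """Ratio-normalised weighted mean difference mu1_hat - mu0_hat."""
    t = z == 1
    mu1 = float(np.sum(w[t] * y[t]) / np.sum(w[t]))
    mu0 = float(np.sum(w[~t] * y[~t]) / np.sum(w[~t]))
    return mu1 - mu0


def _sandwich_var_theta(
    y: np.ndarray, z: np.ndarray, Xd: np.ndarray, ps: np.ndarray, *, known_ps: bool = False
) -> float:
    """Variance of the Hajek IPTW effect from stacked estimating equations.

    Parameters are (mu1, mu0, alpha) with estimating functions

        psi_1i = Z_i (Y_i - mu1) / e_i
        psi_0i = (1-Z_i)(Y_i - mu0) / (1 - e_i)
        psi_ai = x_i (Z_i - e_i)          (the logistic score)

    and Var(theta_hat) = c' A^{-1} B A^{-T} c / n with
    A = mean(-d psi / d(mu1, mu0, alpha)'), B = mean(psi psi'),
    c = (1, -1, 0, ..., 0).  With ``known_ps=True`` the alpha block is
    dropped, i.e. the score is treated as known — the estimator one would
    (wrongly) use if the estimation step were ignored.
    """
    n, d = Xd.shape
    w1 = z / ps
    w0 = (1.0 - z) / (1.0 - ps)
    mu1 = float(np.sum(w1 * y) / np.sum(w1))
    mu0 = float(np.sum(w0 * y) / np.sum(w0))
    r1 = w1 * (y - mu1)  # psi_1
    r0 = w0 * (y - mu0)  # psi_0
    if known_ps:
        k = 2
        psi = np.column_stack([r1, r0])
        A = np.zeros((2, 2))
        A[0, 0] = np.mean(w1)
        A[1, 1] = np.mean(w0)
    else:
        k = 2 + d
        psi_a = Xd * (z - ps)[:, None]
        psi = np.column_stack([r1, r0, psi_a])
        A = np.zeros((k, k))
        A[0, 0] = np.mean(w1)
        A[1, 1] = np.mean(w0)
        # d psi_1 / d alpha = -Z (Y - mu1) (1-e)/e x  -> negated mean enters A
        A[0, 2:] = np.mean((r1 * (1.0 - ps))[:, None] * Xd, axis=0)
        # d psi_0 / d alpha = +(1-Z)(Y - mu0) e/(1-e) x
        A[1, 2:] = -np.mean((r0 * ps)[:, None] * Xd, axis=0)
        A[2:, 2:] = (Xd * (ps * (1.0 - ps))[:, None]).T @ Xd / n
    B = psi.T @ psi / n
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise EstimationError(
            "singular bread matrix in sandwich variance "
            f"(condition number {np.linalg.cond(A):.3e})"
        ) from None
    c = np.zeros(k)
    c[0], c[1] = 1.0, -1.0
    v = c @ Ainv @ B @ Ainv.T @ c / n
    return float(v)


def _design(data: TrialDataset, covariate_subset: Sequence[str]) -> np.ndarray:
    """Intercept-first design matrix for the propensity model."""
    X = data.covariate_matrix(covariate_subset)
    return np.column_stack([np.ones(data.n), X])


# -- public estimators --------------------------------------------------------


def fit_propensity_logistic(
    data: TrialDataset, covariate_subset: Sequence[str] = ()
) -> PropensityFit:
    """Maximum-likelihood logistic regression of treatment on baseline covariates.

    Fit by IRLS; ``converged`` is True when every score component is below
    1e-8 within 50 iterations and no coefficient exceeds 20 in magnitude
    (the separation heuristic).  With an empty subset the fit is
    intercept-only and every score equals the observed treated fraction.
    """
    data.require_two_per_arm()
    Xd = _design(data, covariate_subset)
    alpha, ps, converged, it = _logit_irls(Xd, data.treatment.astype(float))
    return PropensityFit(
        alpha_hat=alpha,
        ps=ps,
        converged=converged,
        n_iterations=it,
        covariate_names=tuple(covariate_subset),
    )


def compute_iptw_weights(fit: PropensityFit, data: TrialDataset) -> IPTWWeights:
    """w = 1/e for the treated, 1/(1-e) for controls; no truncation."""
    if not fit.converged:
        raise EstimationError(
            "propensity model did not converge (possible separation); "
            "refusing to compute weights"
        )
    if len(fit.ps) != data.n:
        raise EstimationError(f"fit has {len(fit.ps)} scores for {data.n} participants")
    z = data.treatment
    w = np.where(z == 1, 1.0 / fit.ps, 1.0 / (1.0 - fit.ps))
    return IPTWWeights(w=w)


def sandwich_variance_iptw(
    data: TrialDataset, fit: PropensityFit, *, known_ps: bool = False
) -> float:
    """Full sandwich variance of the IPTW effect (see module docstring).

    ``known_ps=True`` drops the propensity-score estimating equations,
    giving the (larger) variance appropriate if the score were known.
    """
    if not fit.converged:
        raise EstimationError("propensity model did not converge")
    data.require_two_per_arm()
    Xd = _design(data, fit.covariate_names)
    return _sandwich_var_theta(
        data.outcome, data.treatment.astype(float), Xd, fit.ps, known_ps=known_ps
    )


def estimate_iptw(
    data: TrialDataset, covariate_subset: Sequence[str]
) -> AdjustedEstimate:
    """IPTW treatment effect with the full-sandwich SE and normal-based CI.

    The point estimate is the Hajek weighted mean difference, equal to the
    treatment slope of a WLS fit of outcome on intercept + treatment.  A
    non-converged propensity fit raises EstimationError — callers running
    simulations should catch it and record a flagged failure.
    """
    fit = fit_propensity_logistic(data, covariate_subset)
    weights = compute_iptw_weights(fit, data)  # raises if not converged
    theta = _hajek_theta(data.outcome, data.treatment, weights.w)
    var = sandwich_variance_iptw(data, fit)
    if not var > 0:
        raise EstimationError(f"non-positive sandwich variance {var}")
    se = float(np.sqrt(var))
    ci_low, ci_high, p = confidence_interval(theta, se, "normal")
    return AdjustedEstimate(
        theta_hat=theta,
        se_hat=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        method="iptw",
        reference_distribution="normal",
        adjusted_covariates=tuple(covariate_subset),
        extra={"propensity_fit": fit, "weights": weights},
    )


def ancova_estimate(
    data: TrialDataset, covariate_subset: Sequence[str]
) -> AdjustedEstimate:
    """OLS of outcome on intercept + treatment + covariates (ANCOVA).

    Model-based SE for the treatment coefficient; t-based CI and p-value
    with ``n - (p + 2)`` residual degrees of freedom.
    """
    data.require_two_per_arm()
    X = np.column_stack(
        [np.ones(data.n), data.treatment, data.covariate_matrix(covariate_subset)]
    )
    beta, cov, df = _ols(X, data.outcome)
    theta = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    if not se > 0:
        raise EstimationError("zero model-based SE (degenerate outcome)")
    ci_low, ci_high, p = confidence_interval(theta, se, "t", residual_df=df)
    return AdjustedEstimate(
        theta_hat=theta,
        se_hat=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        method="regression" if covariate_subset else "unadjusted",
        reference_distribution="t",
        residual_df=df,
        adjusted_covariates=tuple(covariate_subset),
    )


def unadjusted_estimate(data: TrialDataset) -> AdjustedEstimate:
    """Difference in arm means via OLS on treatment only (df = n - 2)."""
    return ancova_estimate(data, ())


def confidence_interval(
    theta_hat: float,
    se: float,
    reference_distribution: str,
    residual_df: int | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Symmetric two-sided CI and Wald p-value under normal or t reference.

    Returns ``(ci_low, ci_high, p_value)`` with the interval
    ``theta_hat +/- q * se``, q the (1+level)/2 quantile.
    """
    if not se > 0:
        raise ConfigurationError(f"se must be positive, got {se}")
    if not 0.0 < level < 1.0:
        raise ConfigurationError(f"level must be in (0,1), got {level}")
    tstat = abs(theta_hat) / se
    if reference_distribution == "normal":
        q = float(special.ndtri(0.5 + level / 2.0))
        p = 2.0 * float(special.ndtr(-tstat))
    elif reference_distribution == "t":
        if residual_df is None or residual_df <= 0:
            raise ConfigurationError("t reference requires a positive residual_df")
        q = _t_quantile(0.5 + level / 2.0, int(residual_df))
        p = 2.0 * float(special.stdtr(int(residual_df), -tstat))
    else:
        raise ConfigurationError(
            f"unknown reference distribution {reference_distribution!r}"
        )
    return theta_hat - q * se, theta_hat + q * se, float(min(p, 1.0))


@lru_cache(maxsize=1024)
def _t_quantile(q: float, df: int) -> float:
    return float(special.stdtrit(df, q))


def bootstrap_se(
    data: TrialDataset,
    method: str,
    covariate_subset: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
):
    """Nonparametric bootstrap SE of the chosen point estimate.

    Resamples participants with replacement; each replicate recomputes the
    estimate from scratch — for IPTW that includes refitting the logistic
    propensity model.  Replicates where an arm has < 2 members or the
    propensity fit fails are discarded and redrawn so exactly ``n_boot``
    valid replicates are used; the discard count is returned.  More than
    50% failed draws aborts with EstimationError.

    Returns ``(se_boot, n_discarded)``.
    """
    if n_boot < 2:
        raise ConfigurationError(f"n_boot must be >= 2, got {n_boot}")
    if method not in ("unadjusted", "regression", "iptw"):
        raise ConfigurationError(f"unknown method {method!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = data.outcome
    z = data.treatment.astype(float)
    X = data.covariate_matrix(covariate_subset)
    n = data.n
    est = np.empty(n_boot)
    got = 0
    attempts = 0
    max_attempts = 2 * n_boot + 100
    while got < n_boot:
        if attempts >= max_attempts:
            raise EstimationError(
                f"unstable bootstrap: {attempts - got} of {attempts} draws failed"
            )
        attempts += 1
        idx = rng.integers(0, n, size=n)
        zb = z[idx]
        n1 = zb.sum()
        if n1 < 2 or n - n1 < 2:
            continue
        yb = y[idx]
        Xb = X[idx]
        try:
            if method == "unadjusted":
                est[got] = yb[zb == 1].mean() - yb[zb == 0].mean()
            elif method == "regression":
                D = np.column_stack([np.ones(n), zb, Xb])
                beta, _, _ = _ols(D, yb)
                est[got] = beta[1]
            else:  # iptw: refit the propensity score on the resample
                D = np.column_stack([np.ones(n), Xb])
                _, ps, converged, _ = _logit_irls(D, zb)
                if not converged:
                    continue
                w = np.where(zb == 1, 1.0 / ps, 1.0 / (1.0 - ps))
                est[got] = _hajek_theta(yb, zb, w)
        except EstimationError:
            continue
        got += 1
    n_discarded = attempts - n_boot
    return float(np.std(est, ddof=1)), n_discarded
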