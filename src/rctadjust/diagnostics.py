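"""Covariate-balance and propensity-score overlap diagnostics.

Randomization guarantees balance in expectation, not in any one trial; the
standardized difference quantifies per-covariate imbalance on a pooled-SD
scale, and the overlap report counts participants whose estimated
propensity score falls outside the range common to both arms.  Both are
computed on the unweighted sample, matching how such diagnostics are
reported alongside an IPTW analysis of a randomized trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import TrialDataset
from .estimators import PropensityFit
from .exceptions import EstimationError, ValidationError

__all__ = ["BalanceReport", "standardized_difference", "ps_overlap", "balance_report"]


@dataclass(frozen=True)
class BalanceReport:
    """Balance and overlap summary for one trial.

    ``std_differences`` maps covariate name -> standardized difference
    (treated minus control; NaN when both arm variances are zero).
    ``ps_median`` / ``ps_range`` are per-arm summaries of the fitted
    propensity score, keyed ``"treated"`` and ``"control"``.
    ``non_overlap_count`` counts participants whose score lies outside the
    intersection of the two arms' score ranges.
    """

    std_differences: dict[str, float]
    ps_median: dict[str, float]
    ps_range: dict[str, tuple[float, float]]
    non_overlap_count: int
    non_overlap_fraction: float


def _is_binary(x: np.ndarray) -> bool:
    return bool(np.isin(x, (0.0, 1.0)).all())


def standardized_difference(data: TrialDataset, covariate: str) -> float:
    """(mean_T - mean_C) / sqrt((s2_T + s2_C)/2), treated minus control.

    For a 0/1 covariate each arm's variance is p(1-p).  Returns NaN (with
    no silent zero) when both arm variances vanish and the means agree;
    raises when the scale is zero but the means differ, since the
    difference is then undefined on this scale.
    """
    data.require_two_per_arm()
    x = data.covariate_matrix([covariate])[:, 0]
    t = data.treatment == 1
    xt, xc = x[t], x[~t]
    if _is_binary(x):
        pt, pc = xt.mean(), xc.mean()
        s2t, s2c = pt * (1 - pt), pc * (1 - pc)
        diff = pt - pc
    else:
        s2t, s2c = xt.var(ddof=1), xc.var(ddof=1)
        diff = xt.mean() - xc.mean()
    denom = math.sqrt((s2t + s2c) / 2.0)
    if denom == 0.0:
        if diff == 0.0:
            return float("nan")
        raise EstimationError(
            f"standardized difference of {covariate!r} undefined: zero pooled "
            "variance with unequal arm means"
        )
    return float(diff / denom)


def ps_overlap(fit: PropensityFit, data: TrialDataset) -> BalanceReport:
    """Propensity-score overlap report (no standardized differences).

    The non-overlap region is everything outside
    ``[max(min per arm), min(max per arm)]``; a participant of either arm
    with a score strictly outside that interval is counted.  Disjoint arm
    ranges therefore count every participant.
    """
    if not fit.converged:
        raise EstimationError("propensity model did not converge")
    t = data.treatment == 1
    if t.all() or (~t).all():
        raise ValidationError("both arms must be non-empty")
    ps_t, ps_c = fit.ps[t], fit.ps[~t]
    lo = max(ps_t.min(), ps_c.min())
    hi = min(ps_t.max(), ps_c.max())
    if lo > hi:  # disjoint ranges: no common support at all
        count = data.n
    else:
        count = int(np.sum((fit.ps < lo) | (fit.ps > hi)))
    return BalanceReport(
        std_differences={},
        ps_median={"treated": float(np.median(ps_t)), "control": float(np.median(ps_c))},
        ps_range={
            "treated": (float(ps_t.min()), float(ps_t.max())),
            "control": (float(ps_c.min()), float(ps_c.max())),
        },
        non_overlap_count=count,
        non_overlap_fraction=count / data.n,
    )


def balance_report(fit: PropensityFit, data: TrialDataset) -> BalanceReport:
    """Full report: standardized differences for the fit's covariates plus
    the propensity-score overlap summary."""
    rep = ps_overlap(fit, data)
    sdiffs = {c: standardized_difference(data, c) for c in fit.covariate_names}
    return BalanceReport(
        std_differences=sdiffs,
        ps_median=rep.ps_median,
        ps_range=rep.ps_range,
        non_overlap_count=rep.non_overlap_count,
        non_overlap_fraction=rep.non_overlap_fraction,
    )
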