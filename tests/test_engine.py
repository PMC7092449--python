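"""Monte-Carlo engine: replicate analysis, aggregation, grid execution."""

import math

import numpy as np
import pytest

from rctadjust.core import write_results_table
from rctadjust.engine import ReplicateRecord, ScenarioResult, aggregate_scenario, run_grid, run_replicate
from rctadjust.estimators import estimate_iptw
from rctadjust.exceptions import EstimationError
from rctadjust.simulate import ScenarioConfig, generate_continuous_trial


def test_zero_noise_replicate_recovers_theta_exactly():
    cfg = ScenarioConfig(n=24, adjust_set=("C1",), beta=(0.0,) * 6, error_sd=0.0, seed=2)
    data = generate_continuous_trial(cfg)
    records = run_replicate(data, [("C1",)], theta_true=5.0)
    for r in records:
        assert not r.failed
        assert r.theta_hat == pytest.approx(5.0, abs=1e-9)
        # the CI degenerates to a point here; allow floating round-off
        assert r.ci_low - 1e-9 <= 5.0 <= r.ci_high + 1e-9


def test_engine_record_equals_direct_estimator_call():
    cfg = ScenarioConfig(n=60, adjust_set=("C1", "C2"), seed=11)
    data = generate_continuous_trial(cfg)
    records = run_replicate(data, [("C1", "C2")], theta_true=5.0)
    rec = next(r for r in records if r.method == "iptw")
    est = estimate_iptw(data, ("C1", "C2"))
    assert rec.theta_hat == est.theta_hat and rec.se_hat == est.se_hat
    assert rec.ci_low == est.ci_low and rec.ci_high == est.ci_high


def test_iptw_and_regression_close_but_not_identical():
    cfg = ScenarioConfig(n=200, adjust_set=("C1", "C2"), seed=13)
    data = generate_continuous_trial(cfg)
    records = {r.method: r for r in run_replicate(data, [("C1", "C2")], 5.0)}
    diff = records["iptw"].theta_hat - records["regression"].theta_hat
    assert diff != 0.0
    assert abs(diff) < records["regression"].se_hat


def _fake_records(thetas, covered, method="iptw", adjust=("C1",)):
    return [
        ReplicateRecord(method=method, adjust_set=adjust, theta_hat=t, se_hat=1.0,
                        ci_low=t - 2, ci_high=t + 2, covered=c)
        for t, c in zip(thetas, covered)
    ]


def test_aggregate_all_covered_gives_100_pct():
    cfg = ScenarioConfig(n=40, adjust_set=("C1",), n_reps=4, seed=0)
    recs = _fake_records([4.0, 5.0, 6.0, 5.5], [True] * 4)
    res = aggregate_scenario(recs, cfg, "iptw", ("C1",))
    assert res.coverage_pct == 100.0 and res.mc_se_coverage == 0.0


def test_aggregate_unbiased_records_give_zero_bias():
    cfg = ScenarioConfig(n=40, adjust_set=("C1",), n_reps=3, seed=0)
    recs = _fake_records([5.0, 5.0, 5.0], [True, False, True])
    res = aggregate_scenario(recs, cfg, "iptw", ("C1",))
    assert res.pct_bias == 0.0
    assert res.coverage_pct == pytest.approx(200 / 3)


def test_aggregate_matches_brute_force_reaggregation():
    cfg = ScenarioConfig(n=40, adjust_set=("C1",), n_reps=6, seed=1)
    rng = np.random.default_rng(3)
    thetas = rng.normal(5, 1.5, 6)
    covered = rng.random(6) < 0.9
    recs = _fake_records(list(thetas), list(covered))
    recs.append(ReplicateRecord(method="iptw", adjust_set=("C1",), failed=True))
    res = aggregate_scenario(recs, cfg, "iptw", ("C1",))
    assert res.n_failed_reps == 1
    assert res.mean_theta == pytest.approx(thetas.mean())
    assert res.empirical_se == pytest.approx(thetas.std(ddof=1))
    assert res.pct_bias == pytest.approx((thetas.mean() - 5) / 5 * 100)
    assert res.coverage_pct == pytest.approx(covered.mean() * 100)
    c = covered.mean()
    assert res.mc_se_coverage == pytest.approx(math.sqrt(c * (1 - c) / 6) * 100)
    assert res.se_ratio == pytest.approx(1.0 / thetas.std(ddof=1))


def test_aggregate_requires_two_successes():
    cfg = ScenarioConfig(n=40, adjust_set=("C1",), n_reps=2, seed=0)
    recs = [ReplicateRecord(method="iptw", adjust_set=("C1",), failed=True)] * 2
    with pytest.raises(EstimationError, match="successful"):
        aggregate_scenario(recs, cfg, "iptw", ("C1",))


def test_failed_analysis_is_flagged_not_skipped():
    cfg = ScenarioConfig(n=30, adjust_set=("C1",), seed=2)
    data = generate_continuous_trial(cfg)
    from rctadjust.core import TrialDataset

    sep = TrialDataset(data.subject_id, data.treatment, data.outcome,
                       data.treatment.astype(float).reshape(-1, 1), ("d",))
    records = run_replicate(sep, [("d",)], 5.0)
    by_method = {r.method: r for r in records}
    assert by_method["iptw"].failed and "converge" in by_method["iptw"].failure_reason
    assert not by_method["unadjusted"].failed


def test_smoke_grid_writes_rows(tmp_path):
    res = run_grid([ScenarioConfig(n=40, adjust_set=("C1",), n_reps=10, seed=5)])
    assert {r.method for r in res} == {"unadjusted", "regression", "iptw"}
    assert all(r.n_reps == 10 for r in res)
    out = tmp_path / "res.csv"
    write_results_table([r.to_row() for r in res], out)
    assert out.read_text().count("\n") == 4  # header + 3 method rows


def test_grid_is_deterministic():
    grid = [ScenarioConfig(n=40, adjust_set=a, n_reps=25, seed=8)
            for a in (("C1",), ("C1", "C2"))]
    a = run_grid(grid)
    b = run_grid(grid)
    assert [r.to_row() for r in a] == [r.to_row() for r in b]


def test_shared_datasets_give_identical_unadjusted_cells():
    """Scenario cells at the same n share replicates, so the unadjusted
    analysis is numerically identical across adjustment sets."""
    grid = [ScenarioConfig(n=40, adjust_set=a, n_reps=30, seed=9)
            for a in (("C1",), ("C1", "C2"))]
    res = run_grid(grid)
    unadj = [r for r in res if r.method == "unadjusted"]
    assert len(unadj) == 2
    assert unadj[0].mean_theta == unadj[1].mean_theta
    assert unadj[0].empirical_se == unadj[1].empirical_se


def test_coverage_band_flagging():
    kwargs = dict(scenario="s", n=40, method="iptw", adjust_set=("C1",), mean_theta=5.0,
                  pct_bias=0.0, mean_se=1.0, empirical_se=1.0, se_ratio=1.0,
                  mc_se_coverage=0.5, n_failed_reps=0, n_reps=2000)
    assert ScenarioResult(coverage_pct=93.9, **kwargs).coverage_flag == "low"
    assert ScenarioResult(coverage_pct=95.0, **kwargs).coverage_flag == ""
    assert ScenarioResult(coverage_pct=96.2, **kwargs).coverage_flag == "high"


def test_bootstrap_within_engine_smoke():
    res = run_grid([ScenarioConfig(n=40, adjust_set=("C1",), n_reps=5, seed=3)],
                   with_bootstrap=True, n_boot=30)
    for r in res:
        assert r.mean_bootstrap_se is not None and r.mean_bootstrap_se > 0
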