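import numpy as np
import pandas as pd
import pytest

from panclock import (combined_predictor, cox_regression, km_logrank,
                      quartile_dummies, roc_auc_at_horizon, stratify)
from panclock.simulate import SurvivalParams, simulate_survival


def _km_at(curve: pd.DataFrame, t: float) -> float:
    mask = curve["time"] <= t
    return float(curve.loc[mask, "survival"].iloc[-1])


def test_km_product_limit_hand_example():
    res = km_logrank([5, 10, 15], [1, 1, 0], ["all", "all", "all"])
    curve = res.curves["all"]
    assert _km_at(curve, 5) == pytest.approx(2 / 3)
    assert _km_at(curve, 10) == pytest.approx(1 / 3)
    # censoring at t=15 leaves the curve unchanged
    assert _km_at(curve, 15) == pytest.approx(1 / 3)
    assert res.logrank_p is None  # single group: test omitted


def test_km_without_censoring_equals_empirical_survival(rng):
    times = rng.exponential(100, size=40)
    res = km_logrank(times, np.ones(40, int), ["g"] * 40)
    curve = res.curves["g"]
    for t in np.quantile(times, [0.2, 0.5, 0.8]):
        assert _km_at(curve, t) == pytest.approx((times > t).mean())


def test_identical_groups_logrank_null():
    times = np.r_[np.arange(1, 21), np.arange(1, 21)]
    events = np.ones(40, int)
    groups = ["a"] * 20 + ["b"] * 20
    res = km_logrank(times, events, groups)
    assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
    assert res.logrank_p == pytest.approx(1.0, abs=1e-9)


def test_logrank_p_matches_permutation_null(rng):
    from lifelines.statistics import multivariate_logrank_test
    n = 30
    times = rng.exponential(50, n)
    events = rng.random(n) < 0.8
    groups = np.array(["a"] * 15 + ["b"] * 15)
    obs = multivariate_logrank_test(times, groups, events)
    count = 0
    n_perm = 1000
    for _ in range(n_perm):
        stat = multivariate_logrank_test(times, rng.permutation(groups),
                                         events).test_statistic
        count += stat >= obs.test_statistic
    p_perm = (count + 1) / (n_perm + 1)
    assert abs(p_perm - obs.p_value) < 3 * np.sqrt(0.25 / n_perm) + 0.02


def test_protective_score_orders_km_curves(rng):
    n = 400
    score = rng.standard_normal(n)
    t, e = simulate_survival(score, np.zeros(n),
                             SurvivalParams(beta_clock=1.0, censor_rate=0.1),
                             rng)
    labels = stratify(pd.Series(score), "quartile")
    res = km_logrank(t, e, labels.to_numpy())
    mid = np.median(t)
    # higher score = higher hazard here, so the Q4 curve sits below Q1
    assert _km_at(res.curves["Q4"], mid) < _km_at(res.curves["Q1"], mid)
    assert res.logrank_p < 0.001


def test_cox_degenerate_covariate_rejected(rng):
    times = rng.exponential(10, 20)
    with pytest.raises(ValueError, match="degenerate"):
        cox_regression(times, np.ones(20, int),
                       pd.DataFrame({"c": np.ones(20)}))


def test_quartile_dummies_reference_q1():
    labels = pd.Series(["Q1", "Q2", "Q3", "Q4"])
    d = quartile_dummies(labels)
    assert list(d.columns) == ["Q2_vs_Q1", "Q3_vs_Q1", "Q4_vs_Q1"]
    assert d.sum().tolist() == [1, 1, 1]


def test_auc_perfect_separation_and_pairwise_oracle(rng):
    # two deaths in year 1 with high scores, two long-term survivors, low scores
    auc = roc_auc_at_horizon([0.9, 0.8, 0.2, 0.1],
                             [300, 330, 2400, 2500], [1, 1, 0, 0], 1825).auc
    assert auc == 1.0

    scores = rng.normal(size=60)
    times = rng.exponential(1500, 60)
    events = (rng.random(60) < 0.7).astype(int)
    try:
        res = roc_auc_at_horizon(scores, times, events, 1825)
    except ValueError:
        pytest.skip("degenerate draw")
    case = (events == 1) & (times <= 1825)
    control = times > 1825
    num = 0.0
    for sc in scores[case]:
        for sn in scores[control]:
            num += 1.0 if sc > sn else (0.5 if sc == sn else 0.0)
    assert res.auc == pytest.approx(num / (case.sum() * control.sum()))


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=100)
    times = rng.exponential(1500, 100)
    events = np.ones(100, int)
    a1 = roc_auc_at_horizon(scores, times, events, 1825).auc
    a2 = roc_auc_at_horizon(np.exp(3 * scores) + 7, times, events, 1825).auc
    assert a1 == pytest.approx(a2)


def test_auc_requires_cases_and_controls():
    with pytest.raises(ValueError, match="case"):
        roc_auc_at_horizon([1, 2], [100, 200], [0, 0], 1825)


def test_combined_model_nested_and_additive(rng):
    n = 800
    score = rng.standard_normal(n)
    stage = rng.integers(1, 5, n).astype(float)
    params = SurvivalParams(baseline_hazard=8e-5, beta_clock=0.8,
                            beta_stage=0.6, censor_rate=0.1)
    t, e = simulate_survival(score, stage, params, rng)
    auc_score = roc_auc_at_horizon(score, t, e, 1825).auc
    auc_stage = roc_auc_at_horizon(stage, t, e, 1825).auc
    lp = combined_predictor(score, stage, t, e)
    auc_comb = roc_auc_at_horizon(lp.to_numpy(), t, e, 1825).auc
    assert auc_comb > auc_score and auc_comb > auc_stage

    # pure-noise stage cannot hurt the combined model by more than noise
    t2, e2 = simulate_survival(score, np.zeros(n),
                               SurvivalParams(baseline_hazard=4e-4,
                                              beta_clock=0.8, censor_rate=0.1),
                               rng)
    noise_stage = rng.integers(1, 5, n).astype(float)
    lp2 = combined_predictor(score, noise_stage, t2, e2)
    auc_only = roc_auc_at_horizon(score, t2, e2, 1825).auc
    auc_comb2 = roc_auc_at_horizon(lp2.to_numpy(), t2, e2, 1825).auc
    assert auc_comb2 >= auc_only - 0.02


def test_combined_model_constant_score_reduces_to_stage(rng):
    n = 300
    stage = rng.integers(1, 5, n).astype(float)
    t, e = simulate_survival(np.zeros(n), stage,
                             SurvivalParams(baseline_hazard=8e-5,
                                            beta_stage=0.7, censor_rate=0.1),
                             rng)
    lp = combined_predictor(np.ones(n), stage, t, e)
    assert roc_auc_at_horizon(lp.to_numpy(), t, e, 1825).auc == \
        pytest.approx(roc_auc_at_horizon(stage, t, e, 1825).auc)
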