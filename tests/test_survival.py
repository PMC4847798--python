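"""Kaplan–Meier / log-rank and the Cox screening cascade.

Cross-checks against independent oracles: a hand-computed observed-minus-
expected log-rank on a six-subject example, an explicit partial-likelihood
maximizer for single-covariate Cox fits, and simulations with known truth.
"""

import numpy as np
import pandas as pd
import pytest

from svzprox.survival import (
    CollinearityError,
    ZeroVarianceError,
    cox_multivariate,
    cox_univariate,
    km_logrank,
    screen_then_multivariate,
)

import oracles


def surv_frame(times, events, x, endpoint="os", **extra):
    frame = pd.DataFrame({"os_days": times, "os_event": events})
    frame["pfs_days"], frame["pfs_event"] = frame["os_days"], frame["os_event"]
    if isinstance(x, dict):
        for k, v in x.items():
            frame[k] = v
    else:
        frame["x"] = x
    for k, v in extra.items():
        frame[k] = v
    return frame


def exp_cohort(rng, n, hr=1.0, censor_frac=0.0, rate=0.01):
    """Two-group exponential survival with a known rate ratio."""
    x = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1.0 / (rate * hr**x))
    if censor_frac > 0:
        c = rng.exponential(1.0 / (rate * censor_frac / (1 - censor_frac)), n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
    else:
        times, events = t, np.ones(n, dtype=int)
    return times, events, x


# -- Kaplan–Meier / log-rank ---------------------------------------------


def test_km_without_censoring_equals_empirical_survival(rng):
    times = rng.exponential(100, 40).round(1)
    times += np.arange(40) * 1e-4  # break ties
    events = np.ones(40, dtype=int)
    group = np.repeat([0, 1], 20)
    res = km_logrank(times, events, group)
    for g in (0, 1):
        curve = res.curves[g]
        own = np.sort(times[group == g])
        for t, s in zip(curve["time"], curve["survival"]):
            if t == 0:
                continue
            empirical = np.mean(own > t)
            assert s == pytest.approx(empirical, abs=1e-12)
        surv = curve["survival"].to_numpy()
        assert surv[0] <= 1.0 + 1e-12 and np.all(np.diff(surv) <= 1e-12)


def test_identical_groups_give_null_logrank():
    times = [5, 10, 15, 20, 25]
    res = km_logrank(times * 2, [1, 1, 0, 1, 0] * 2, [0] * 5 + [1] * 5)
    assert res.chi_square == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_logrank_matches_hand_computation():
    """Six subjects, mixed censoring: chi-square equals the hand-computed
    observed-minus-expected form, (2 - 1.7333)^2 / 0.96222 = 0.073903."""
    times = [1, 3, 5, 2, 4, 6]
    events = [1, 0, 1, 1, 1, 0]
    group = [0, 0, 0, 1, 1, 1]
    res = km_logrank(times, events, group)
    chi2_oracle, _ = oracles.logrank_two_group(times, events, group)
    assert chi2_oracle == pytest.approx(0.0739027, abs=1e-6)
    assert res.chi_square == pytest.approx(chi2_oracle, abs=1e-9)


def test_logrank_input_validation():
    with pytest.raises(ValueError):
        km_logrank([1, 2, 3], [1, 1, 0], [0, 0, 0])  # one group only
    with pytest.raises(ValueError):
        km_logrank([1, 2], [0, 0], [0, 1])  # all censored


# -- Cox fits ------------------------------------------------------------


def test_cox_univariate_matches_partial_likelihood_oracle(rng):
    """The fitted coefficient maximizes the partial likelihood: compare with
    an independent 1-D maximizer on untied data."""
    times, events, x = exp_cohort(rng, 150, hr=2.0, censor_frac=0.2)
    times = times + rng.random(150) * 1e-6  # guarantee no ties
    est = cox_univariate(surv_frame(times, events, x), "os", "x")
    beta_oracle = oracles.cox_beta_no_ties(times, events, x)
    assert np.log(est.hr) == pytest.approx(beta_oracle, abs=1e-4)
    assert est.ci_lower < est.hr < est.ci_upper


def test_cox_null_and_known_rate_ratio():
    rng = np.random.default_rng(0)
    t0, e0, x0 = exp_cohort(rng, 2000, hr=1.0)
    null = cox_univariate(surv_frame(t0, e0, x0), "os", "x")
    assert 0.85 <= null.hr <= 1.18
    t2, e2, x2 = exp_cohort(rng, 2000, hr=2.0, censor_frac=0.2)
    known = cox_univariate(surv_frame(t2, e2, x2), "os", "x")
    assert 1.8 <= known.hr <= 2.2
    assert known.ci_lower < known.hr < known.ci_upper


def test_cox_error_conditions(rng):
    times, events, x = exp_cohort(rng, 60, hr=1.5)
    with pytest.raises(ZeroVarianceError):
        cox_univariate(surv_frame(times, events, np.ones(60)), "os", "x")
    frame = surv_frame(times, events, {"a": x, "b": x})  # duplicated column
    with pytest.raises(CollinearityError):
        cox_multivariate(frame, "os", ["a", "b"])
    with pytest.raises(CollinearityError):
        cox_multivariate(frame, "os", ["a", "a"])


def test_multivariate_with_two_planted_effects(rng):
    """Joint fit separates a true log-2 effect from a null covariate."""
    n = 2000
    a = (rng.random(n) < 0.5).astype(int)
    b = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2) * a)))
    frame = surv_frame(t, np.ones(n, dtype=int), {"a": a, "b": b})
    est = {e.covariate: e for e in cox_multivariate(frame, "os", ["a", "b"])}
    assert est["a"].ci_lower > 1.0
    assert est["b"].ci_lower < 1.0 < est["b"].ci_upper


# -- the screen → multivariate cascade -----------------------------------


def test_screen_gates_multivariate_at_alpha(rng):
    n = 400
    a = (rng.random(n) < 0.5).astype(int)  # strong effect
    b = (rng.random(n) < 0.5).astype(int)  # null
    t = rng.exponential(1.0 / (0.01 * np.exp(1.0 * a)))
    frame = surv_frame(t, np.ones(n, dtype=int), {"a": a, "b": b})
    report = screen_then_multivariate(frame, "os", ["a", "b"], alpha=0.05)
    assert all(e.p_value < 0.05 for e in report.univariate if e.covariate in report.selected)
    assert all(e.p_value >= 0.05 for e in report.univariate if e.covariate not in report.selected)
    assert {e.covariate for e in report.multivariate} == set(report.selected)


def test_screen_single_survivor_equals_univariate(rng):
    times, events, x = exp_cohort(rng, 300, hr=3.0)
    null = (rng.random(300) < 0.5).astype(int)
    rng2 = np.random.default_rng(5)
    frame = surv_frame(times, events, {"x": x, "z": null})
    report = screen_then_multivariate(frame, "os", ["x", "z"], alpha=1e-6)
    if report.selected == ["x"]:
        uni = {e.covariate: e for e in report.univariate}["x"]
        multi = report.multivariate[0]
        assert multi.hr == pytest.approx(uni.hr, abs=1e-8)
        assert multi.p_value == pytest.approx(uni.p_value, abs=1e-8)


def test_screen_with_no_survivor_reports_empty_model(rng):
    times, events, _ = exp_cohort(rng, 80, hr=1.0)
    null = (np.arange(80) % 2).astype(int)
    frame = surv_frame(times, events, {"z": null})
    report = screen_then_multivariate(frame, "os", ["z"], alpha=1e-9)
    assert report.selected == [] and report.multivariate == []
    assert any("no candidate" in n for n in report.notes)


def test_screen_survives_per_covariate_failures(rng):
    times, events, x = exp_cohort(rng, 100, hr=2.0)
    frame = surv_frame(times, events, {"x": x, "flat": np.zeros(100)})
    report = screen_then_multivariate(frame, "os", ["x", "flat"])
    assert [e.covariate for e in report.univariate] == ["x"]
    assert any("flat" in n for n in report.notes)
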