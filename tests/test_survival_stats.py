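"""Survival estimators: oracles by hand computation, enumeration, and
lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest

from normes import (
    CategoryCuts,
    Cohort,
    StatsConfig,
    SubjectRecord,
    auc_difference_bootstrap,
    categorize,
    censoring_km,
    compute_category_cuts,
    continuous_nri,
    evaluate_markers,
    fit_univariate_ph,
    km_curve,
    pairwise_logrank,
    predicted_risk_at,
    td_auc,
)
from normes.survival_stats import (
    DAYS_PER_YEAR,
    PHFit,
    _fit_ph_arrays,
    _nri_point,
    _td_auc_arrays,
    _weighted_auc,
    product_limit,
)

from conftest import make_survival_data


def cohort_from(time, event, weight=None, event_lc=None, **markers):
    n = len(time)
    frame = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "time_days": time,
        "event_all_cause": event,
        "event_lung_cancer": event_lc if event_lc is not None else np.zeros(n, int),
        "weight": weight if weight is not None else np.ones(n),
    })
    for k, v in markers.items():
        frame[k] = v
    return Cohort(frame)


# ---------------------------------------------------------------------------
# categories


def test_categorize_rules():
    cuts = CategoryCuts(5.4, 12.0)  # typical screening-cohort origES cuts
    assert categorize([7.0], cuts)[0] == "medium"
    assert categorize([5.4], cuts)[0] == "medium"  # boundary joins medium
    assert categorize([12.0], cuts)[0] == "medium"
    assert categorize([5.39], cuts)[0] == "low"
    assert categorize([12.01], cuts)[0] == "high"


def test_category_split_matches_sort_oracle():
    scores = np.arange(1.0, 101.0)
    cuts = compute_category_cuts(scores)
    s = np.sort(scores)
    assert cuts.p60 == pytest.approx(np.quantile(s, 0.6))
    cats = categorize(scores, cuts)
    assert (cats == "low").sum() == 60
    assert (cats == "medium").sum() == 20
    assert (cats == "high").sum() == 20


def test_weighted_cuts_match_replication():
    rng = np.random.default_rng(0)
    scores = rng.gamma(2, 3, 50)
    w = rng.integers(1, 4, 50)
    cw = compute_category_cuts(scores, w.astype(float))
    cr = compute_category_cuts(np.repeat(scores, w))
    assert cw.p60 == pytest.approx(cr.p60, abs=0.3)
    assert cw.p80 == pytest.approx(cr.p80, abs=0.3)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_censoring_equals_ecdf():
    time = np.array([5.0, 3.0, 8.0, 1.0, 8.0])
    event = np.ones(5, int)
    km = product_limit(time, event)
    for t in (0.5, 1.0, 3.0, 5.0, 8.0, 9.0):
        assert km.survival_at(t) == pytest.approx((time > t).mean(), abs=1e-12)


def test_km_all_censored_is_one():
    km = product_limit(np.array([3.0, 5.0]), np.array([0, 0]))
    assert km.survival_at(100.0) == 1.0


def test_km_hand_example():
    """Ten subjects with interleaved censoring; product-limit values worked
    out by hand: S = 9/10, 9/10*6/8, *4/5, *2/3."""
    time = np.array([2, 3, 4, 4, 5, 7, 8, 9, 10, 10], float)
    event = np.array([1, 0, 1, 1, 0, 1, 0, 1, 0, 0])
    km = product_limit(time, event)
    np.testing.assert_allclose(km.times, [2, 4, 7, 9])
    np.testing.assert_allclose(km.survival, [0.9, 0.675, 0.54, 0.36], atol=1e-12)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter

    time, event, _, _ = make_survival_data(200, seed=4, censor_frac=0.4)
    km = product_limit(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    for t in np.quantile(time, [0.2, 0.5, 0.8]):
        assert km.survival_at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-10)


def test_integer_weight_km_equals_replication():
    rng = np.random.default_rng(5)
    time = rng.uniform(1, 100, 30)
    event = rng.integers(0, 2, 30)
    w = rng.integers(1, 5, 30).astype(float)
    km_w = product_limit(time, event, w)
    km_r = product_limit(np.repeat(time, w.astype(int)),
                         np.repeat(event, w.astype(int)))
    np.testing.assert_allclose(km_w.times, km_r.times)
    np.testing.assert_allclose(km_w.survival, km_r.survival, atol=1e-12)


def test_censoring_km_inverts_roles():
    time = np.array([2, 3, 4, 4, 5, 7, 8, 9, 10, 10], float)
    event = np.array([1, 0, 1, 1, 0, 1, 0, 1, 0, 0])
    c = cohort_from(time, event)
    g = censoring_km(c)
    oracle = product_limit(time, 1 - event)
    np.testing.assert_allclose(g.times, oracle.times)
    np.testing.assert_allclose(g.survival, oracle.survival)


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_null():
    time, event, _, _ = make_survival_data(40, seed=6)
    c = cohort_from(np.concatenate([time, time]),
                    np.concatenate([event, event]),
                    es=np.concatenate([np.zeros(40), np.ones(40)]))
    cats = np.array(["low"] * 40 + ["high"] * 40)
    (res,) = pairwise_logrank(c, cats)
    assert res.chi2 == pytest.approx(0.0, abs=1e-9)
    assert res.p == pytest.approx(1.0, abs=1e-9)


def test_three_groups_three_comparisons():
    time, event, _, m = make_survival_data(90, seed=7)
    c = cohort_from(time, event, es=m)
    cats = categorize(m, compute_category_cuts(m))
    results = pairwise_logrank(c, cats)
    assert len(results) == 3
    assert all(r.significant == (r.p < 0.0167) for r in results)


def test_two_group_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test

    time, event, _, m = make_survival_data(120, seed=8, beta=0.6)
    g = m > 0
    c = cohort_from(time, event, es=m)
    cats = np.where(g, "high", "low")
    (res,) = pairwise_logrank(c, cats)
    ll = logrank_test(time[~g], time[g], event[~g], event[g])
    assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
    assert res.p == pytest.approx(ll.p_value, rel=1e-6)


# ---------------------------------------------------------------------------
# time-dependent AUC


def test_td_auc_perfect_separation():
    time = np.array([100, 200, 300, 2000, 2500, 3000], float)
    event = np.array([1, 1, 1, 0, 0, 0])
    marker = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
    c = cohort_from(time, event, es=marker)
    assert td_auc(c, "es", 365.0).auc == 1.0


def test_td_auc_constant_marker_is_half():
    time, event, _, _ = make_survival_data(50, seed=9)
    c = cohort_from(time, event, es=np.ones(50))
    assert td_auc(c, "es", 500.0).auc == 0.5


def brute_force_auc(time, event, w, m, h):
    case = (time <= h) & (event == 1)
    ctrl = time > h
    num = den = 0.0
    for i in np.flatnonzero(case):
        for j in np.flatnonzero(ctrl):
            pair_w = w[i] * w[j]
            den += pair_w
            if m[i] > m[j]:
                num += pair_w
            elif m[i] == m[j]:
                num += 0.5 * pair_w
    return num / den


def test_td_auc_matches_enumeration_oracle_uncensored():
    rng = np.random.default_rng(10)
    for rep in range(20):
        n = int(rng.integers(10, 60))
        time = rng.uniform(1, 1000, n)
        event = np.ones(n, int)
        m = np.round(rng.normal(size=n), 1)  # rounding makes ties likely
        w = rng.integers(1, 4, n).astype(float)
        c = cohort_from(time, event, weight=w, es=m)
        h = float(np.quantile(time, 0.5))
        if not ((time <= h).any() and (time > h).any()):
            continue
        assert td_auc(c, "es", h).auc == pytest.approx(
            brute_force_auc(time, event, w, m, h), abs=1e-12)


def test_td_auc_sign_flip():
    time, event, w, m = make_survival_data(80, seed=11, beta=0.5)
    c = cohort_from(time, event, es=m, neg=-m)
    h = 800.0
    a = td_auc(c, "es", h).auc
    b = td_auc(c, "neg", h).auc
    assert a + b == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= a <= 1.0


def test_td_auc_requires_cases_and_controls():
    c = cohort_from(np.array([100.0, 200.0]), np.array([0, 0]), es=np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        td_auc(c, "es", 500.0)


def test_auc_diff_zero_for_identical_markers():
    time, event, _, m = make_survival_data(100, seed=12, beta=0.5)
    c = cohort_from(time, event, a=m, b=m)
    res = auc_difference_bootstrap(c, "a", "b", 500.0, StatsConfig(n_boot=50, seed=0))
    assert res.diff == 0.0
    assert res.ci_low <= 0.0 <= res.ci_high


def test_auc_diff_bootstrap_deterministic():
    time, event, _, m = make_survival_data(100, seed=13, beta=0.5)
    rng = np.random.default_rng(14)
    c = cohort_from(time, event, a=m + rng.normal(0, 1, 100), b=m)
    cfg = StatsConfig(n_boot=80, seed=21)
    r1 = auc_difference_bootstrap(c, "a", "b", 500.0, cfg)
    r2 = auc_difference_bootstrap(c, "a", "b", 500.0, cfg)
    assert (r1.ci_low, r1.ci_high, r1.diff) == (r2.ci_low, r2.ci_high, r2.diff)


def test_auc_diff_detects_known_advantage():
    """Marker B is the true risk driver, A a noise-corrupted copy: at a
    five-year horizon the bootstrap CI of AUC(B) - AUC(A) excludes 0."""
    rng = np.random.default_rng(151)
    n = 2000
    time, event, w, m = make_survival_data(n, seed=15, beta=0.8, censor_frac=0.2)
    c = cohort_from(time, event, a=m + rng.normal(0, 2.0, n), b=m)
    res = auc_difference_bootstrap(c, "a", "b", 5 * DAYS_PER_YEAR,
                                   StatsConfig(n_boot=500, seed=15))
    assert res.diff > 0
    assert res.ci_low > 0


# ---------------------------------------------------------------------------
# proportional hazards


def test_ph_null_marker_beta_near_zero():
    time, event, w, m = make_survival_data(1000, seed=16, beta=0.0)
    fit = _fit_ph_arrays(time, event, w, m)
    assert abs(fit.beta) < 3 * fit.se


def test_ph_recovers_true_beta():
    time, event, w, m = make_survival_data(1000, seed=17, beta=0.5)
    fit = _fit_ph_arrays(time, event, w, m)
    assert abs(fit.beta - 0.5) < 3 * fit.se


def test_ph_weight_scale_invariance():
    time, event, w, m = make_survival_data(300, seed=18, beta=0.5)
    f1 = _fit_ph_arrays(time, event, w, m)
    f2 = _fit_ph_arrays(time, event, 2.0 * w, m)
    assert f1.beta == pytest.approx(f2.beta, abs=1e-10)


def test_ph_matches_lifelines():
    from lifelines import CoxPHFitter

    time, event, _, m = make_survival_data(300, seed=19, beta=0.5)
    fit = _fit_ph_arrays(time, event, np.ones_like(time), m)
    df = pd.DataFrame({"T": time, "E": event, "m": m})
    cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
    assert fit.beta == pytest.approx(float(cph.params_["m"]), abs=1e-6)
    assert fit.se == pytest.approx(float(cph.standard_errors_["m"]), abs=1e-6)


def test_ph_constant_marker_rejected():
    time, event, w, _ = make_survival_data(50, seed=20)
    with pytest.raises(ValueError, match="constant"):
        _fit_ph_arrays(time, event, w, np.ones_like(time))


def test_predicted_risk_closed_form():
    fit = PHFit(beta=0.7, se=0.1, event_times=np.array([100.0, 200.0]),
                cum_hazard=np.array([0.01, 0.03]), n_iter=3)
    # before the first event time the cumulative hazard is zero
    assert predicted_risk_at(fit, 2.0, 50.0) == 0.0
    expect = 1.0 - np.exp(-0.03 * np.exp(0.7 * 2.0))
    assert predicted_risk_at(fit, 2.0, 250.0) == pytest.approx(expect, rel=1e-12)
    # beta = 0 gives the same risk for every marker value
    fit0 = PHFit(beta=0.0, se=0.1, event_times=fit.event_times,
                 cum_hazard=fit.cum_hazard, n_iter=1)
    assert predicted_risk_at(fit0, -5.0, 250.0) == predicted_risk_at(fit0, 5.0, 250.0)


# ---------------------------------------------------------------------------
# continuous NRI


def test_nri_identical_markers_zero():
    time, event, _, m = make_survival_data(60, seed=21, beta=0.5)
    c = cohort_from(time, event, a=m, b=m.copy())
    with pytest.warns(UserWarning, match="identical"):
        res = continuous_nri(c, "a", "b", 500.0, StatsConfig(n_boot=5, seed=0), ci=False)
    assert res.nri_percent == 0.0


def test_nri_antisymmetric_under_swap():
    rng = np.random.default_rng(221)
    time, event, _, m = make_survival_data(80, seed=22, beta=0.5)
    c = cohort_from(time, event, a=m + rng.normal(0, 1, 80), b=m)
    fwd = continuous_nri(c, "a", "b", 700.0, ci=False)
    rev = continuous_nri(c, "b", "a", 700.0, ci=False)
    assert fwd.nri_percent == pytest.approx(-rev.nri_percent, abs=1e-10)


def test_nri_uncensored_counting_oracle():
    """With no censoring the KM-based NRI reduces to direct counting of
    up/down moves among events and non-events at the horizon."""
    rng = np.random.default_rng(23)
    n = 40
    m_old = rng.normal(size=n)
    m_new = m_old + rng.normal(0, 1.5, n)
    time = rng.uniform(1, 1000, n)
    event = np.ones(n, int)
    w = rng.integers(1, 3, n).astype(float)
    h = 450.0

    fit_old = _fit_ph_arrays(time, event, w, m_old)
    fit_new = _fit_ph_arrays(time, event, w, m_new)
    p_old = predicted_risk_at(fit_old, m_old, h)
    p_new = predicted_risk_at(fit_new, m_new, h)
    nri, _ = _nri_point(time, event, w, p_old, p_new, h)

    up = p_new > p_old
    down = p_new < p_old
    ev = time <= h
    expect = 100.0 * (
        (w[up & ev].sum() - w[down & ev].sum()) / w[ev].sum()
        + (w[down & ~ev].sum() - w[up & ~ev].sum()) / w[~ev].sum()
    )
    assert nri == pytest.approx(expect, abs=1e-10)


# ---------------------------------------------------------------------------
# cohort container and table driver


def test_cohort_validation():
    with pytest.raises(ValueError, match="unique"):
        cohort_frame = pd.DataFrame({
            "id": ["a", "a"], "time_days": [1.0, 2.0],
            "event_all_cause": [1, 0], "event_lung_cancer": [0, 0],
            "weight": [1.0, 1.0]})
        Cohort(cohort_frame)
    with pytest.raises(ValueError, match="lung-cancer"):
        Cohort(pd.DataFrame({
            "id": ["a"], "time_days": [1.0], "event_all_cause": [0],
            "event_lung_cancer": [1], "weight": [1.0]}))


def test_cohort_records_and_csv_round_trip(tmp_path):
    records = [SubjectRecord(id=f"s{i}", time_days=100.0 + i,
                             event_all_cause=i % 2, event_lung_cancer=0,
                             weight=1.0, markers={"origES": float(i)})
               for i in range(6)]
    c = Cohort.from_records(records)
    path = tmp_path / "cohort.csv"
    c.to_csv(path)
    back = Cohort.read_csv(path)
    assert back.n == 6 and back.design == "full"
    np.testing.assert_allclose(back.marker("origES"), np.arange(6.0))


def test_lung_cancer_cause_censors_other_deaths():
    time = np.array([100.0, 200.0, 300.0])
    c = cohort_from(time, np.array([1, 1, 0]), event_lc=np.array([1, 0, 0]), es=time)
    t, e, w = c.survival_arrays("lung_cancer")
    np.testing.assert_array_equal(e, [1, 0, 0])
    np.testing.assert_array_equal(t, time)


def test_evaluate_markers_identical_markers_and_shape():
    time, event, _, m = make_survival_data(250, seed=24, beta=0.5)
    c = cohort_from(time, event, origES=m, normES=m.copy())
    cfg = StatsConfig(n_boot=20, horizons_years=(1, 2), seed=1)
    table = evaluate_markers(c, config=cfg, causes=("all_cause",))
    assert len(table) == 2
    assert (table["diff_auc"] == 0.0).all()
    assert (table["nri_percent"] == 0.0).all()
    assert {"auc_old", "auc_new", "diff_auc", "nri_percent",
            "nri_lo", "nri_hi"} <= set(table.columns)


def test_evaluate_markers_null_cohort_covers_half():
    rng = np.random.default_rng(25)
    time, event, _, _ = make_survival_data(400, seed=25, beta=0.0)
    c = cohort_from(time, event, origES=rng.normal(size=400), normES=rng.normal(size=400))
    cfg = StatsConfig(n_boot=60, horizons_years=(3,), seed=2)
    table = evaluate_markers(c, config=cfg, causes=("all_cause",))
    row = table.iloc[0]
    assert row.auc_old_lo <= 0.5 <= row.auc_old_hi
    assert row.auc_new_lo <= 0.5 <= row.auc_new_hi
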