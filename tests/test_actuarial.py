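"""Actuarial response rates, effective sample sizes and latency summaries."""

import itertools

import numpy as np
import pytest

from cordrbe.actuarial import (
    actuarial_response,
    apply_actuarial,
    effective_sample_size,
    latency_summary,
)
from cordrbe.records import ActuarialEstimate, AnimalRecord

from conftest import make_experiment


@pytest.mark.parametrize(
    "times,events,p,var",
    [
        ([100, 150], [1, 1], 1.0, 0.0),  # everyone responds, no censoring
        ([300, 300], [0, 0], 0.0, 0.0),  # no events at all
        # one event at 150, one censored at 200: S(300)=0.5,
        # Greenwood var = 0.25 * 1/(2*1) = 0.125
        ([150, 200], [1, 0], 0.5, 0.125),
    ],
)
def test_product_limit_hand_cases(times, events, p, var):
    est = actuarial_response(times, events, horizon=300)
    assert est.p_act == pytest.approx(p)
    assert est.var_act == pytest.approx(var)


def test_empty_input_rejected():
    with pytest.raises(ValueError, match="empty"):
        actuarial_response([], [], horizon=300)


def test_immature_followup_flagged():
    est = actuarial_response([100, 120], [0, 0], horizon=300)
    assert est.p_act == 0.0
    assert est.immature_followup


def test_effective_counts_formula():
    est = ActuarialEstimate(p_act=0.5, var_act=0.05, n_at_risk=10)
    n_eff, r_eff = effective_sample_size(est, n_raw=10, r_raw=5)
    assert n_eff == pytest.approx(5.0)
    assert r_eff == pytest.approx(2.5)


def test_no_censoring_is_identity():
    """Binomial variance p(1-p)/n implies n_eff = n_raw exactly."""
    p, n = 0.4, 5
    est = ActuarialEstimate(p_act=p, var_act=p * (1 - p) / n, n_at_risk=n)
    n_eff, r_eff = effective_sample_size(est, n_raw=n, r_raw=2)
    assert n_eff == pytest.approx(n)
    assert r_eff == pytest.approx(2.0)


def test_degenerate_rates_fall_back_to_raw():
    est = ActuarialEstimate(p_act=0.0, var_act=0.0, n_at_risk=5)
    assert effective_sample_size(est, 5, 0) == (5.0, 0.0)
    est = ActuarialEstimate(p_act=1.0, var_act=0.0, n_at_risk=5)
    assert effective_sample_size(est, 5, 5) == (5.0, 5.0)


def test_zero_variance_intermediate_rate_warns():
    est = ActuarialEstimate(p_act=0.5, var_act=0.0, n_at_risk=4)
    with pytest.warns(UserWarning, match="raw counts"):
        n_eff, r_eff = effective_sample_size(est, 4, 2)
    assert (n_eff, r_eff) == (4.0, 2.0)


def test_n_eff_never_exceeds_n_raw_and_shrinks_with_censoring():
    """Censoring before a later event loses information: n_eff drops
    below n_raw, while complete follow-up keeps n_eff = n_raw."""
    full = actuarial_response([150, 250, 300, 300], [1, 1, 0, 0], 300)
    n_full, _ = effective_sample_size(full, 4, 2)
    assert n_full == pytest.approx(4.0)

    cens = actuarial_response([150, 200, 250, 300], [1, 0, 1, 0], 300)
    n_cens, r_cens = effective_sample_size(cens, 4, 2)
    assert n_cens < 4.0
    assert 0 <= r_cens <= n_cens


def test_agrees_with_lifelines_survival():
    """Independent cross-check: product-limit survivor function against
    lifelines, Greenwood variance against its event table."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(3, 12)
        times = rng.integers(30, 301, size=n).astype(float)
        events = rng.integers(0, 2, size=n)
        if events.sum() == 0:
            continue
        est = actuarial_response(times, events, horizon=300)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        s_ll = float(kmf.predict(300.0))
        assert 1.0 - est.p_act == pytest.approx(s_ll, abs=1e-12)
        tab = kmf.event_table
        ev = tab[tab["observed"] > 0]
        gw = float(
            (ev["observed"] / (ev["at_risk"] * (ev["at_risk"] - ev["observed"]))).replace(
                [np.inf], 0
            ).sum()
        )
        expected_var = min(s_ll**2 * gw, 0.25)
        assert est.var_act == pytest.approx(expected_var, abs=1e-12)


def brute_force_product_limit(times, events, horizon):
    """Direct textbook evaluation used as an oracle: walk the sorted
    distinct event times, shrinking the risk set by every observation
    that has left."""
    times = list(map(float, times))
    s = 1.0
    gw = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1 and t <= horizon}):
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        s *= 1 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
    return 1 - s, (s**2 * gw if s > 0 else 0.0)


def test_matches_brute_force_on_all_small_configs():
    """Exhaustive check over every <=3-animal configuration of times in
    {60, 150, 300} and event indicators."""
    grid = [60.0, 150.0, 300.0]
    for n in (1, 2, 3):
        for times in itertools.product(grid, repeat=n):
            for events in itertools.product((0, 1), repeat=n):
                est = actuarial_response(times, events, horizon=300)
                p, var = brute_force_product_limit(times, events, 300)
                assert est.p_act == pytest.approx(p, abs=1e-12)
                assert est.var_act == pytest.approx(min(var, 0.25), abs=1e-12)


def test_latency_summary_ignores_censored():
    recs = [
        AnimalRecord("a1", "e", 17.5, 1, 120.0),
        AnimalRecord("a2", "e", 17.5, 1, 180.0),
        AnimalRecord("a3", "e", 17.5, 0, 300.0),
    ]
    s = latency_summary(recs)
    assert (s.min_days, s.mean_days, s.max_days) == (120.0, 150.0, 180.0)
    assert s.n_responders == 2


def test_latency_single_responder_and_empty_sentinel():
    one = latency_summary([AnimalRecord("a", "e", 17.5, 1, 140.0)])
    assert one.min_days == one.mean_days == one.max_days == 140.0
    empty = latency_summary([AnimalRecord("a", "e", 17.5, 0, 300.0)])
    assert empty.n_responders == 0
    assert np.isnan(empty.mean_days)


def test_apply_actuarial_complete_followup_equals_raw():
    exp = make_experiment([(15.0, 5, 0), (17.5, 5, 3), (20.0, 5, 5)])
    apply_actuarial(exp)
    for grp in exp.groups:
        assert grp.n_eff == pytest.approx(grp.n_raw)
        assert grp.r_eff == pytest.approx(grp.r_raw)
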