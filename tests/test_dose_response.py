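"""Maximum-likelihood dose-response fits, TD50, fallback SE and Fieller limits."""

import math

import numpy as np
import pytest

from cordrbe.actuarial import apply_actuarial
from cordrbe.dose_response import (
    binomial_loglik,
    estimate_se_fallback,
    fieller_cl,
    fit_dose_response,
)
from cordrbe.simulate import SimulationConfig, simulate_experiment

from conftest import make_experiment


def test_symmetric_groups_force_midpoint_td50(symmetric_experiment):
    """1/5 at 18 Gy and 4/5 at 22 Gy are mirror images around 20 Gy."""
    fit = fit_dose_response(symmetric_experiment, use_effective=False)
    assert fit.converged
    assert fit.td50 == pytest.approx(20.0, abs=1e-6)


def test_fitted_probability_at_td50_is_half(sobp36_experiment):
    fit = fit_dose_response(sobp36_experiment, use_effective=False)
    p = 1.0 / (1.0 + math.exp(-(fit.b0 + fit.b1 * fit.td50)))
    assert p == pytest.approx(0.5, abs=1e-12)


def test_loglik_is_a_maximum(sobp36_experiment):
    fit = fit_dose_response(sobp36_experiment, use_effective=False)
    doses = np.array([g.total_dose for g in sobp36_experiment.groups])
    n = np.array([g.n_raw for g in sobp36_experiment.groups], dtype=float)
    r = np.array([g.r_raw for g in sobp36_experiment.groups], dtype=float)
    rng = np.random.default_rng(11)
    for _ in range(100):
        b0 = fit.b0 + rng.normal(0, 0.5)
        b1 = fit.b1 + rng.normal(0, 0.1)
        assert binomial_loglik(b0, b1, doses, n, r) <= fit.loglik + 1e-9


def test_separation_branch_uses_midpoint_and_fallback_se():
    exp = make_experiment([(15.0, 5, 0), (16.0, 5, 5)])
    fit = fit_dose_response(exp, use_effective=False)
    assert fit.se_estimated
    assert fit.td50 == pytest.approx(15.5)
    assert fit.se_td50 == pytest.approx(0.25)
    assert fit.cl90 is None


def test_quasi_separation_falls_back_to_estimated_se():
    """A single partial group between pure 0% and 100% groups leaves the
    slope nearly unbounded; the likelihood SE is then unusable and the
    25%-of-dose-gap estimate is reported instead."""
    exp = make_experiment(
        [(25.5, 5, 0), (28.5, 5, 1), (31.5, 5, 5), (34.5, 5, 5)], let_value=36.0
    )
    fit = fit_dose_response(exp, use_effective=False)
    assert fit.se_estimated
    assert fit.se_td50 == pytest.approx(1.5)  # 0.25 * (31.5 - 25.5)
    assert fit.cl90 is None
    assert 28.5 < fit.td50 < 31.5


@pytest.mark.parametrize("counts", [[(15.0, 5, 0), (16.0, 5, 0)], [(15.0, 5, 5), (16.0, 5, 5)]])
def test_uninformative_pattern_rejected(counts):
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_dose_response(make_experiment(counts), use_effective=False)


def test_effective_equals_raw_gives_identical_fit(sobp36_experiment):
    apply_actuarial(sobp36_experiment)  # complete follow-up: eff == raw
    f_eff = fit_dose_response(sobp36_experiment, use_effective=True)
    f_raw = fit_dose_response(sobp36_experiment, use_effective=False)
    assert f_eff.td50 == pytest.approx(f_raw.td50, abs=1e-9)
    assert f_eff.se_td50 == pytest.approx(f_raw.se_td50, abs=1e-9)


def test_probit_link_agrees_near_midpoint(sobp36_experiment):
    logit = fit_dose_response(sobp36_experiment, use_effective=False, link="logit")
    probit = fit_dose_response(sobp36_experiment, use_effective=False, link="probit")
    assert probit.td50 == pytest.approx(logit.td50, rel=0.02)


def test_recovers_true_td50_on_simulated_cohort():
    """High-LET-style design (doses 15-20 Gy, true TD50 17.5 Gy)."""
    config = SimulationConfig(
        true_td50={(99.0, 6): 17.5},
        slope_b1=1.8,
        dose_levels={(99.0, 6): [15.0, 16.0, 17.0, 18.0, 19.0, 20.0]},
        dropout_prob=0.0,
        seed=5,
    )
    exp = simulate_experiment(config, 99.0, 6)
    apply_actuarial(exp)
    fit = fit_dose_response(exp)
    assert abs(fit.td50 - 17.5) < 4.0 * fit.se_td50


def test_fallback_rule_arithmetic(sobp36_experiment):
    """Highest 0% level 25.5 Gy, lowest 100% level 31.5 Gy -> 1.5 Gy."""
    assert estimate_se_fallback(sobp36_experiment) == pytest.approx(1.5)


def test_fallback_small_gap():
    exp = make_experiment([(15.0, 5, 0), (16.0, 5, 5)])
    assert estimate_se_fallback(exp) == pytest.approx(0.25)


def test_fallback_requires_both_extremes():
    exp = make_experiment([(15.0, 5, 1), (16.0, 5, 5)])
    with pytest.raises(ValueError, match="0% and a 100%"):
        estimate_se_fallback(exp)


def test_fallback_overlap_uses_50pct_bracket():
    # a 100% group below a 0% group: fall back to the doses bracketing 50%
    exp = make_experiment([(15.0, 5, 0), (16.0, 5, 5), (17.0, 5, 2), (18.0, 5, 5)])
    # zeros max = 15, fulls min = 16 -> positive gap, plain rule applies
    assert estimate_se_fallback(exp) == pytest.approx(0.25)
    exp2 = make_experiment([(15.0, 5, 5), (16.0, 5, 0), (17.0, 5, 2), (18.0, 5, 5)])
    # overlap: bracket 50% -> below {16}, above {15.. wait doses<0.5 resp}:
    # responses: 15:100%, 16:0%, 17:40%, 18:100%; below-50% doses {16,17},
    # above {15,18}; bracket = 18 - 17 = 1 -> 0.25
    assert estimate_se_fallback(exp2) == pytest.approx(0.25)


def test_fieller_degenerate_zero_se():
    assert fieller_cl(3.0, 0.0, 2.0, 0.0) == pytest.approx((1.5, 1.5))


def test_fieller_unbounded_when_denominator_near_zero():
    low, high = fieller_cl(1.0, 0.1, 0.1, 1.0)
    assert math.isinf(low) and math.isinf(high)


def test_fieller_narrows_as_ses_shrink():
    widths = []
    for scale in (1.0, 0.5, 0.25, 0.1):
        lo, hi = fieller_cl(57.0, 2.0 * scale, 39.1, 0.4 * scale)
        widths.append(hi - lo)
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_fieller_contains_ratio():
    lo, hi = fieller_cl(57.0, 2.0, 39.1, 0.4, cov=0.1)
    assert lo < 57.0 / 39.1 < hi
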