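"""Model-vs-experiment RBE benchmarking statistics."""

import numpy as np
import pandas as pd
import pytest

from cordrbe.compare import (
    fit_ab_vs_let,
    fit_rbe_let_poly,
    percent_deviation,
    region_average,
    slope_ratio,
)

from conftest import ALPHA_BETA, SOBP_LETS


def table(lets, rbes, nfx=6, se=None):
    df = pd.DataFrame({"let_kev_um": lets, "n_fractions": nfx, "rbe": rbes})
    if se is not None:
        df["se"] = se
    return df


def test_identical_tables_deviate_zero():
    t = table([16, 21, 36], [1.5, 1.7, 2.0])
    devs = percent_deviation(t, t)
    assert np.allclose(devs["deviation_pct"], 0.0)


def test_uniform_underestimate():
    exp = table([16, 21], [2.0, 4.0])
    model = table([16, 21], [1.8, 3.6])
    devs = percent_deviation(model, exp)
    assert np.allclose(devs["deviation_pct"], [-10.0, -10.0])
    mean, sd = region_average(devs, [16, 21])
    assert mean == pytest.approx(-10.0)
    assert sd == pytest.approx(0.0)


def test_key_mismatch_lists_missing_keys():
    exp = table([16, 21], [2.0, 4.0])
    model = table([16, 45], [1.8, 3.6])
    with pytest.raises(KeyError, match="45"):
        percent_deviation(model, exp)


def test_duplicate_keys_rejected():
    t = pd.DataFrame(
        {"let_kev_um": [16, 16], "n_fractions": [6, 6], "rbe": [1.5, 1.6]}
    )
    with pytest.raises(ValueError, match="duplicate"):
        percent_deviation(t, t.drop_duplicates(subset=["let_kev_um", "n_fractions"]))


def test_single_point_region_has_zero_sd():
    mean, sd = region_average([-7.5])
    assert (mean, sd) == (-7.5, 0.0)


def test_union_mean_is_weighted_combination():
    exp = table([16, 21, 36, 45], [1.5, 1.7, 2.0, 2.1])
    model = table([16, 21, 36, 45], [1.4, 1.5, 1.9, 2.1])
    devs = percent_deviation(model, exp)
    m_ent, _ = region_average(devs, [16, 21])
    m_sobp, _ = region_average(devs, [36, 45])
    m_all, _ = region_average(devs, [16, 21, 36, 45])
    assert m_all == pytest.approx((2 * m_ent + 2 * m_sobp) / 4)


def test_antisymmetry_relation():
    """Swapping roles flips the sign up to the denominator change:
    dev(model, exp) = -dev(exp, model) * (rbe_model / rbe_exp)."""
    exp = table([36, 45], [2.0, 2.2])
    model = table([36, 45], [1.7, 2.5])
    fwd = percent_deviation(model, exp)["deviation_pct"].to_numpy()
    rev = percent_deviation(exp, model)["deviation_pct"].to_numpy()
    ratio = model["rbe"].to_numpy() / exp["rbe"].to_numpy()
    assert np.allclose(fwd, -rev * ratio)


def test_poly_fit_exact_cases():
    line = table([10, 20, 30], [1.0, 2.0, 3.0])
    coef = fit_rbe_let_poly(line, order=1)
    assert coef == pytest.approx([0.0, 0.1], abs=1e-12)
    para = table([10, 20, 30], [1.0, 2.5, 3.0])
    coef2 = fit_rbe_let_poly(para, order=2)
    x = np.array([10.0, 20.0, 30.0])
    fitted = coef2[0] + coef2[1] * x + coef2[2] * x**2
    assert np.allclose(fitted, [1.0, 2.5, 3.0])


def test_poly_fit_weights_matter():
    t = table([10, 20, 30, 40], [1.0, 2.1, 2.9, 4.2], se=[0.05, 0.5, 0.5, 0.05])
    weighted = fit_rbe_let_poly(t, order=1)
    unweighted = fit_rbe_let_poly(t.drop(columns="se"), order=1)
    assert not np.allclose(weighted, unweighted)


def test_slope_ratio_identity_and_half():
    exp = table(SOBP_LETS, [2.0, 2.1, 3.1, 3.3])
    ratio, se = slope_ratio(exp, exp, SOBP_LETS)
    assert ratio == pytest.approx(1.0)
    x = np.asarray(SOBP_LETS, dtype=float)
    shallow = table(SOBP_LETS, 2.0 + 0.5 * 0.02 * (x - x[0]))
    steep = table(SOBP_LETS, 2.0 + 0.02 * (x - x[0]))
    ratio2, _ = slope_ratio(shallow, steep, SOBP_LETS)
    assert ratio2 == pytest.approx(0.5)


def test_slope_ratio_matches_hand_computed_ols():
    x = np.array([36.0, 45.0, 66.0, 99.0])
    ye = np.array([2.0, 2.2, 3.0, 3.4])
    ym = np.array([2.1, 2.2, 2.5, 2.9])

    def ols_slope(y):
        xc = x - x.mean()
        return float((xc * (y - y.mean())).sum() / (xc**2).sum())

    ratio, se = slope_ratio(table(x, ym), table(x, ye), x.tolist())
    assert ratio == pytest.approx(ols_slope(ym) / ols_slope(ye), rel=1e-12)
    assert se > 0


def test_slope_ratio_affine_let_invariance():
    x = np.array([36.0, 45.0, 66.0, 99.0])
    ye, ym = [2.0, 2.2, 3.0, 3.4], [2.1, 2.2, 2.5, 2.9]
    r1, _ = slope_ratio(table(x, ym), table(x, ye), x.tolist())
    x2 = 3.0 * x + 7.0
    r2, _ = slope_ratio(table(x2, ym), table(x2, ye), x2.tolist())
    assert r2 == pytest.approx(r1, rel=1e-12)


def test_slope_ratio_near_flat_experiment_rejected():
    exp = table(SOBP_LETS, [2.0, 2.0, 2.0, 2.0])
    model = table(SOBP_LETS, [2.0, 2.5, 3.0, 3.5])
    with pytest.raises(ValueError, match="unstable"):
        slope_ratio(model, exp, SOBP_LETS)


def test_slope_ratio_alternative_methods_run():
    exp = table(SOBP_LETS, [2.0, 2.2, 3.0, 3.4])
    model = table(SOBP_LETS, [2.1, 2.2, 2.5, 2.9])
    r_line, _ = slope_ratio(model, exp, SOBP_LETS, method="line")
    r_poly, se_poly = slope_ratio(model, exp, SOBP_LETS, method="poly_deriv")
    r_end, _ = slope_ratio(model, exp, SOBP_LETS, method="endpoint")
    assert np.isnan(se_poly)
    # all three see the same qualitative shallowness of the model
    assert r_line < 1 and r_end < 1


def ab_table():
    rows = [
        {"let_kev_um": let, "alpha_beta": ab, "se": se}
        for let, (ab, se) in ALPHA_BETA.items()
        if let > 0
    ]
    return pd.DataFrame(rows)


def test_ab_regression_two_points_exact():
    t = pd.DataFrame({"let_kev_um": [16.0, 99.0], "alpha_beta": [6.9, 30.8]})
    res = fit_ab_vs_let(t)
    assert res["slope"] == pytest.approx((30.8 - 6.9) / (99.0 - 16.0))


def test_ab_regression_published_values_increase_with_let():
    res = fit_ab_vs_let(ab_table())
    assert res["slope"] > 0


def test_ab_regression_flat_table_has_zero_slope():
    t = pd.DataFrame({"let_kev_um": [16.0, 45.0, 99.0], "alpha_beta": [8.0] * 3})
    res = fit_ab_vs_let(t)
    assert res["slope"] == pytest.approx(0.0, abs=1e-12)
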