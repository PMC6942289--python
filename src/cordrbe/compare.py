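"""Benchmarking model-predicted RBE tables against experimental values.

Model predictions (e.g. from amorphous-track-structure RBE models) and
experimental RBE estimates are compared point-by-point at matched
(LET, fraction-number) keys:

    deviation_i [%] = 100 * (RBE_model,i - RBE_exp,i) / RBE_exp,i,

so a model that underestimates the measured RBE produces negative
deviations.  Deviations are then averaged (mean +/- sample SD) over LET
regions — the entrance channel upstream of the spread-out Bragg peak
versus the in-peak positions — or over fraction numbers at fixed LET.

The steepness of the RBE rise with LET is compared through the ratio of
straight-line regression slopes over a region, and the LET dependence of
alpha/beta through weighted linear regression.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "percent_deviation",
    "region_average",
    "fit_rbe_let_poly",
    "slope_ratio",
    "fit_ab_vs_let",
    "compare_tables",
]

_KEYS = ["let_kev_um", "n_fractions"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns: {missing}")


def percent_deviation(model: pd.DataFrame, experiment: pd.DataFrame) -> pd.DataFrame:
    """Per-point percent deviation of model RBE from experimental RBE.

    Both tables need ``let_kev_um``, ``n_fractions`` and ``rbe`` columns
    with unique keys; every model key must have an experimental partner.
    Returns the merged table with a ``deviation_pct`` column.
    """
    _require_columns(model, _KEYS + ["rbe"], "model")
    _require_columns(experiment, _KEYS + ["rbe"], "experiment")
    for name, df in (("model", model), ("experiment", experiment)):
        if df.duplicated(subset=_KEYS).any():
            raise ValueError(f"{name} table has duplicate (LET, fractions) keys")
    merged = model.merge(
        experiment[_KEYS + ["rbe"]],
        on=_KEYS,
        how="left",
        suffixes=("_model", "_exp"),
    )
    unmatched = merged[merged["rbe_exp"].isna()]
    if len(unmatched):
        keys = list(unmatched[_KEYS].itertuples(index=False, name=None))
        raise KeyError(f"no experimental RBE for keys: {keys}")
    merged["deviation_pct"] = (
        100.0 * (merged["rbe_model"] - merged["rbe_exp"]) / merged["rbe_exp"]
    )
    return merged


def region_average(
    devs: pd.DataFrame | Sequence[float], region: Sequence[float] | None = None
) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of per-point deviations over a region.

    ``devs`` is either a deviation table from :func:`percent_deviation`
    (then ``region`` selects LET values) or a bare sequence of percent
    deviations (then ``region`` is ignored).  A single point has no
    dispersion estimate; its SD is reported as 0.
    """
    if isinstance(devs, pd.DataFrame):
        sel = devs
        if region is not None:
            sel = devs[devs["let_kev_um"].isin(region)]
        values = sel["deviation_pct"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(devs), dtype=float)
    if values.size == 0:
        raise ValueError("region contains no deviation points")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def fit_rbe_let_poly(table: pd.DataFrame, order: int = 2) -> np.ndarray:
    """Least-squares polynomial of RBE against LET.

    Inverse-variance weights are used when an ``se`` column with positive
    values is present.  Returns coefficients in increasing-power order
    (numpy polynomial convention).
    """
    _require_columns(table, ["let_kev_um", "rbe"], "rbe")
    if len(table) < order + 1:
        raise ValueError(f"need at least {order + 1} points for order {order}")
    x = table["let_kev_um"].to_numpy(dtype=float)
    y = table["rbe"].to_numpy(dtype=float)
    w = None
    if "se" in table.columns and table["se"].notna().all() and (table["se"] > 0).all():
        w = 1.0 / table["se"].to_numpy(dtype=float)  # polyfit weights are 1/sigma
    series = np.polynomial.Polynomial.fit(x, y, deg=order, w=w)
    return series.convert().coef


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1])


def slope_ratio(
    model: pd.DataFrame,
    experiment: pd.DataFrame,
    region: Sequence[float],
    method: str = "line",
    order: int = 2,
) -> tuple[float, float]:
    """Ratio of the model's RBE-vs-LET slope to the experimental one.

    ``method``:

    - ``"line"`` (default): straight-line OLS slope over the region
      points; SE of the ratio propagates both slope SEs.
    - ``"poly_deriv"``: derivative of the order-``order`` polynomial fit,
      evaluated at the region's mean LET; no SE (reported as nan).
    - ``"endpoint"``: difference quotient between the lowest- and
      highest-LET region points; no SE.
    """
    devs_m = model[model["let_kev_um"].isin(region)].sort_values("let_kev_um")
    devs_e = experiment[experiment["let_kev_um"].isin(region)].sort_values("let_kev_um")
    if len(devs_m) < 2 or len(devs_e) < 2:
        raise ValueError("need at least two points per table within the region")
    xm, ym = devs_m["let_kev_um"].to_numpy(float), devs_m["rbe"].to_numpy(float)
    xe, ye = devs_e["let_kev_um"].to_numpy(float), devs_e["rbe"].to_numpy(float)

    if method == "line":
        sm_, se_m = _ols_slope(xm, ym)
        se_, se_e = _ols_slope(xe, ye)
    elif method == "poly_deriv":
        pm = np.polynomial.Polynomial.fit(xm, ym, deg=order).convert()
        pe = np.polynomial.Polynomial.fit(xe, ye, deg=order).convert()
        at = float(np.mean(region))
        sm_, se_ = float(pm.deriv()(at)), float(pe.deriv()(at))
        se_m = se_e = math.nan
    elif method == "endpoint":
        sm_ = (ym[-1] - ym[0]) / (xm[-1] - xm[0])
        se_ = (ye[-1] - ye[0]) / (xe[-1] - xe[0])
        se_m = se_e = math.nan
    else:
        raise ValueError(f"unknown method {method!r}")

    if abs(se_) < 1e-12 * max(abs(sm_), 1.0):
        raise ValueError("experimental slope is near zero; ratio unstable")
    ratio = sm_ / se_
    if math.isnan(se_m) or math.isnan(se_e):
        return ratio, math.nan
    se_ratio = abs(ratio) * math.sqrt((se_m / sm_) ** 2 + (se_e / se_) ** 2)
    return ratio, se_ratio


def fit_ab_vs_let(ab_table: pd.DataFrame) -> dict:
    """Weighted linear regression of alpha/beta on LET.

    ``ab_table`` columns: ``let_kev_um``, ``alpha_beta`` and optional
    ``se`` (inverse-variance weights).  Returns intercept/slope with SEs.
    """
    _require_columns(ab_table, ["let_kev_um", "alpha_beta"], "alpha/beta")
    if len(ab_table) < 2:
        raise ValueError("need at least two points")
    x = ab_table["let_kev_um"].to_numpy(float)
    y = ab_table["alpha_beta"].to_numpy(float)
    if "se" in ab_table.columns and (ab_table["se"] > 0).all():
        w = 1.0 / ab_table["se"].to_numpy(float) ** 2
    else:
        w = np.ones_like(y)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return {
        "intercept": float(res.params[0]),
        "slope": float(res.params[1]),
        "se_intercept": float(res.bse[0]),
        "se_slope": float(res.bse[1]),
    }


def compare_tables(
    model: pd.DataFrame,
    experiment: pd.DataFrame,
    entrance_lets: Sequence[float],
    sobp_lets: Sequence[float],
    aggregate_over: str = "let",
):
    """Full comparison: per-point deviations, region averages, slope ratio.

    ``aggregate_over`` chooses the averaging axis: ``"let"`` averages the
    per-LET deviations within each region at fixed fraction number (one
    row per Fx), ``"fractions"`` averages over fraction numbers at fixed
    LET (one row per LET).
    """
    from .records import ComparisonResult

    devs = percent_deviation(model, experiment)
    results = []
    if aggregate_over == "let":
        for nfx, sub in devs.groupby("n_fractions"):
            ent = region_average(sub, entrance_lets)
            sobp = region_average(sub, sobp_lets)
            sr = None
            try:
                sr = slope_ratio(
                    model[model["n_fractions"] == nfx],
                    experiment[experiment["n_fractions"] == nfx],
                    sobp_lets,
                )
            except ValueError:
                pass
            results.append(
                ComparisonResult(
                    per_point_deviation_pct=sub["deviation_pct"].tolist(),
                    entrance_mean_pct=ent[0],
                    entrance_sd_pct=ent[1],
                    sobp_mean_pct=sobp[0],
                    sobp_sd_pct=sobp[1],
                    entrance_lets=list(entrance_lets),
                    sobp_lets=list(sobp_lets),
                    slope_ratio=None if sr is None else sr[0],
                    slope_ratio_se=None if sr is None else sr[1],
                )
            )
        return dict(zip((str(k) for k, _ in devs.groupby("n_fractions")), results))
    if aggregate_over == "fractions":
        out = {}
        for let, sub in devs.groupby("let_kev_um"):
            mean, sd = region_average(sub["deviation_pct"].tolist())
            out[str(let)] = {"mean_pct": mean, "sd_pct": sd, "n": len(sub)}
        return out
    raise ValueError(f"unknown aggregation axis {aggregate_over!r}")
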