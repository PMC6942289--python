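"""Relative biological effectiveness as a ratio estimate.

The RBE at a given schedule is the ratio of the photon and carbon-ion
tolerance doses for the same endpoint, RBE = TD50_x / TD50_C.  Its
standard error follows by first-order propagation of the two TD50 errors
(the photon and carbon arms are independent cohorts, so no
cross-covariance), and 90% confidence limits come from Fieller's theorem.

The maximum RBE — the limit for vanishing dose per fraction — is the
analogous ratio of the BED50 values from the joint LQ fits.  In between,
the dose dependence of the RBE follows from LQ isoeffect: a carbon
fraction d_C is biologically matched by the photon fraction d_x solving

    d_x (1 + d_x / (a/b)_x) = RBE_max * d_C (1 + d_C / (a/b)_C),

and RBE(d_C) = d_x / d_C.  This interpolates between RBE_max at d -> 0
and sqrt(RBE_max * (a/b)_x / (a/b)_C) at large doses.
"""

from __future__ import annotations

import math
from typing import Union

from .dose_response import fieller_cl
from .records import LQFit, RBEEstimate, ScheduleTD50

__all__ = [
    "compute_rbe",
    "compute_rbe_max",
    "rbe_vs_dose",
    "rbe_max_from_alpha",
]

_EstimatePair = Union[tuple[float, float], ScheduleTD50]


def _as_pair(x: _EstimatePair) -> tuple[float, float]:
    if isinstance(x, ScheduleTD50):
        return x.td50, x.se_td50
    value, se = x
    return float(value), float(se)


def _ratio_estimate(
    num: float, se_num: float, den: float, se_den: float, level: float
) -> tuple[float, float, tuple[float, float]]:
    if num <= 0 or den <= 0:
        raise ValueError("ratio inputs must be positive")
    ratio = num / den
    se = ratio * math.sqrt((se_num / num) ** 2 + (se_den / den) ** 2)
    cl = fieller_cl(num, se_num, den, se_den, cov=0.0, level=level)
    return ratio, se, cl


def compute_rbe(
    photon: _EstimatePair,
    carbon: _EstimatePair,
    level: float = 0.90,
    let_value: float = math.nan,
    n_fractions: int | None = None,
) -> RBEEstimate:
    """RBE at a fixed fraction number from the TD50 ratio.

    ``photon`` and ``carbon`` are (td50, se) pairs or
    :class:`ScheduleTD50` objects; when both carry fraction numbers they
    must match — an RBE mixes schedules only through the LQ route.
    """
    if isinstance(photon, ScheduleTD50) and isinstance(carbon, ScheduleTD50):
        if photon.n_fractions != carbon.n_fractions:
            raise ValueError(
                "photon and carbon TD50s are at different fraction numbers: "
                f"{photon.n_fractions} vs {carbon.n_fractions}"
            )
        n_fractions = carbon.n_fractions
        if math.isnan(let_value):
            let_value = carbon.let_value
    td_x, se_x = _as_pair(photon)
    td_c, se_c = _as_pair(carbon)
    rbe, se, cl = _ratio_estimate(td_x, se_x, td_c, se_c, level)
    return RBEEstimate(
        rbe=rbe, se=se, cl90=cl, basis="td50_ratio",
        let_value=let_value, n_fractions=n_fractions,
    )


def compute_rbe_max(
    photon: Union[LQFit, tuple[float, float]],
    carbon: Union[LQFit, tuple[float, float]],
    level: float = 0.90,
    let_value: float = math.nan,
) -> RBEEstimate:
    """Maximum RBE (low-dose limit) from the BED50 ratio.

    Photon and carbon BED50s come from independent studies, so the SE
    propagates the two BED50 errors with zero cross-covariance.
    """
    def as_bed(x):
        if isinstance(x, LQFit):
            return x.bed50, x.se_bed50, x.let_value
        return float(x[0]), float(x[1]), math.nan

    bed_x, se_x, _ = as_bed(photon)
    bed_c, se_c, let_c = as_bed(carbon)
    if math.isnan(let_value):
        let_value = let_c
    rbe, se, cl = _ratio_estimate(bed_x, se_x, bed_c, se_c, level)
    return RBEEstimate(
        rbe=rbe, se=se, cl90=cl, basis="bed50_ratio",
        let_value=let_value, n_fractions=None,
    )


def rbe_vs_dose(
    d_carbon: float, rbe_max: float, ab_photon: float, ab_carbon: float
) -> float:
    """RBE at carbon dose per fraction ``d_carbon`` by LQ isoeffect.

    Matches the biologically effective dose per fraction of the carbon
    schedule (scaled by ``rbe_max``) with a photon fraction and returns
    the dose ratio.  Tends to ``rbe_max`` as d -> 0 and to
    ``sqrt(rbe_max * ab_photon / ab_carbon)`` as d -> inf.
    """
    if min(d_carbon, rbe_max, ab_photon, ab_carbon) <= 0:
        raise ValueError("all inputs must be positive")
    bed_per_fx = rbe_max * d_carbon * (1.0 + d_carbon / ab_carbon)
    # rationalized positive root of d(1 + d/ab) = B, stable for small B
    d_photon = 2.0 * bed_per_fx / (
        1.0 + math.sqrt(1.0 + 4.0 * bed_per_fx / ab_photon)
    )
    return d_photon / d_carbon


def rbe_max_from_alpha(alpha_ion: float, alpha_photon: float) -> float:
    """Model-side maximum RBE: ratio of the linear LQ coefficients.

    RBE prediction models report alpha values directly; their low-dose
    RBE limit is alpha_ion / alpha_photon.  Provided for benchmarking
    externally supplied model tables against the experimental
    BED50-ratio estimates.
    """
    if alpha_ion <= 0 or alpha_photon <= 0:
        raise ValueError("alpha values must be positive")
    return alpha_ion / alpha_photon
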