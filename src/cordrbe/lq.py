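"""Joint linear-quadratic isoeffect analysis across fractionation schedules.

In the LQ model an isoeffective schedule of n fractions of dose d
satisfies

    BED = n d (1 + d / (alpha/beta)),

so the tolerance doses TD50 observed at several fraction numbers
constrain both the fractionation sensitivity alpha/beta and the
biologically effective dose at 50% complication probability, BED50.
Here the two parameters are fitted jointly by weighted nonlinear least
squares on the TD50 (dose) scale: for trial (BED50, alpha/beta) the
predicted tolerance dose at n fractions is n times the positive root of

    d (1 + d / (alpha/beta)) = BED50 / n,

and residuals are weighted by the reported TD50 standard errors.  The
parameter covariance comes from the Jacobian at the optimum; 90%
confidence limits use a log-scale delta construction (both parameters
are positive and their sampling distributions right-skewed).

A reciprocal-dose (Fe-plot) fit — weighted linear regression of 1/TD50
on dose per fraction — is provided as a cross-check; for noiseless data
the two routes agree exactly.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .records import LQFit, ScheduleTD50

__all__ = ["bed_from_td50", "invert_bed", "fit_lq"]

_Z90 = 1.6448536269514722


def bed_from_td50(td50: float, n_fractions: int, alpha_beta: float) -> float:
    """Biologically effective dose of a schedule delivering ``td50`` in
    ``n_fractions`` equal fractions: ``td50 * (1 + d/(alpha/beta))`` with
    ``d = td50/n``."""
    if td50 <= 0 or n_fractions <= 0 or alpha_beta <= 0:
        raise ValueError("td50, n_fractions and alpha_beta must be positive")
    d = td50 / n_fractions
    return td50 * (1.0 + d / alpha_beta)


def invert_bed(bed50: float, alpha_beta: float, n_fractions: int) -> float:
    """Total dose over ``n_fractions`` fractions that realises ``bed50``.

    Unique positive root of the per-fraction quadratic
    ``d (1 + d/ab) = bed50 / n``, scaled by n.  Exact inverse of
    :func:`bed_from_td50`.
    """
    if bed50 <= 0 or alpha_beta <= 0 or n_fractions <= 0:
        raise ValueError("all inputs must be positive")
    ab = alpha_beta
    b = bed50 / n_fractions
    # rationalized positive root of d(1 + d/ab) = b, stable for large ab
    d = 2.0 * b / (1.0 + math.sqrt(1.0 + 4.0 * b / ab))
    return n_fractions * d


def _lq_init(nfx: np.ndarray, td50: np.ndarray) -> tuple[float, float]:
    """Starting values from the reciprocal-dose (Fe-plot) regression.

    1/TD50 is linear in dose per fraction: intercept 1/BED50, slope
    1/(ab * BED50).  Exact for noiseless data, so the subsequent
    nonlinear polish starts essentially at the optimum.
    """
    d = td50 / nfx
    y = 1.0 / td50
    slope, intercept = np.polyfit(d, y, 1)
    if intercept <= 0 or slope <= 0:
        # fall back to a broad default when the design is nearly flat
        return float(td50.max() * 1.5), 10.0
    return 1.0 / intercept, intercept / slope


def fit_lq(
    schedules: Sequence[ScheduleTD50],
    level: float = 0.90,
    scale: str = "dose",
) -> LQFit:
    """Joint fit of (BED50, alpha/beta) to TD50s at several fraction numbers.

    Parameters
    ----------
    schedules
        At least two :class:`ScheduleTD50` with distinct fraction
        numbers.  With exactly two the system is exactly determined
        (zero residual) and the SEs are pure error propagation through
        the closed-form solution.
    level
        Confidence level for the log-scale delta limits.
    scale
        ``"dose"`` (default) fits on the TD50 scale using the reported
        SEs as weights; ``"reciprocal"`` fits the Fe-plot linear model
        with transformed weights as a cross-check.
    """
    if len(schedules) < 2:
        raise ValueError("need at least two schedules")
    nfx = np.array([s.n_fractions for s in schedules], dtype=float)
    td50 = np.array([s.td50 for s in schedules], dtype=float)
    se = np.array([s.se_td50 for s in schedules], dtype=float)
    if len(set(nfx.tolist())) < 2:
        raise ValueError("schedules must cover at least two distinct fraction numbers")
    lets = {s.let_value for s in schedules if not math.isnan(s.let_value)}
    let_value = lets.pop() if len(lets) == 1 else math.nan
    modality = schedules[0].modality

    if scale == "reciprocal":
        bed50, ab, cov = _fit_reciprocal(nfx, td50, se)
        resid_norm = 0.0
        converged = True
    elif scale == "dose":
        def residuals(theta: np.ndarray) -> np.ndarray:
            bed, ab = theta
            pred = np.array([invert_bed(bed, ab, int(n)) for n in nfx])
            return (pred - td50) / se

        x0 = np.asarray(_lq_init(nfx, td50))
        sol = least_squares(
            residuals,
            x0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        bed50, ab = sol.x
        jtj = sol.jac.T @ sol.jac
        # weights are taken as true inverse variances: cov = (J'J)^-1
        cov = np.linalg.inv(jtj)
        resid_norm = float(np.sqrt(2.0 * sol.cost))
        converged = bool(sol.success)
        if not converged:
            raise RuntimeError(
                f"LQ fit did not converge (status {sol.status}); residuals "
                f"{residuals(sol.x)}"
            )
    else:
        raise ValueError(f"unknown scale {scale!r}")

    se_bed = float(np.sqrt(cov[0, 0]))
    se_ab = float(np.sqrt(cov[1, 1]))
    z = _z(level)
    return LQFit(
        alpha_beta=float(ab),
        se_alpha_beta=se_ab,
        bed50=float(bed50),
        se_bed50=se_bed,
        cov_ab_bed=float(cov[0, 1]),
        cl90_ab=_log_delta_cl(ab, se_ab, z),
        cl90_bed=_log_delta_cl(bed50, se_bed, z),
        converged=converged,
        residual=resid_norm,
        let_value=let_value,
        modality=modality,
    )


def _z(level: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(0.5 + level / 2.0))


def _log_delta_cl(value: float, se: float, z: float) -> tuple[float, float]:
    """Asymmetric limits from a normal approximation on the log scale."""
    if value <= 0 or se <= 0:
        return (value, value)
    half = z * se / value
    return (value * math.exp(-half), value * math.exp(half))


def _fit_reciprocal(
    nfx: np.ndarray, td50: np.ndarray, se: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Weighted Fe-plot fit: 1/TD50 = a + b * d with a = 1/BED50,
    b = 1/(ab*BED50); parameters and covariance mapped back by the delta
    method."""
    import statsmodels.api as sm

    d = td50 / nfx
    y = 1.0 / td50
    se_y = se / td50**2  # first-order transform of the TD50 errors
    X = sm.add_constant(d)
    res = sm.WLS(y, X, weights=1.0 / se_y**2).fit()
    a, b = res.params
    # cov of (a,b) without the residual-variance rescaling: weights are
    # true inverse variances, as in the dose-scale fit
    cov_ab = np.asarray(res.cov_params()) / res.scale
    bed50 = 1.0 / a
    ab = a / b
    jac = np.array([[-1.0 / a**2, 0.0], [1.0 / b, -a / b**2]])
    cov = jac @ cov_ab @ jac.T
    return float(bed50), float(ab), cov
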