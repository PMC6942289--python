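"""Maximum-likelihood dose-response fitting and Fieller confidence limits.

The complication probability is modelled as a sigmoid in total dose,

    p(D) = 1 / (1 + exp(-(b0 + b1 D)))          (logit link, default)

fitted by maximum likelihood on grouped binomial counts.  The effective
(actuarially corrected) counts are real-valued and enter the likelihood
directly as weights.  The tolerance dose at 50% complication probability
is TD50 = -b0/b1; its standard error comes from the delta method using
the full (b0, b1) covariance, and 90% confidence limits from Fieller's
theorem applied to the ratio -b0/b1.

When the observed responses separate completely (every group at 0% or
100%, with the 0% groups strictly below the 100% groups) the slope is
unidentifiable; TD50 is then taken as the midpoint of the two bracketing
doses and its SE by the fallback rule: 25% of the dose gap between the
neighbouring 0% and 100% response levels.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .records import DoseGroup, DoseResponseFit, Experiment

__all__ = [
    "fit_dose_response",
    "estimate_se_fallback",
    "fieller_cl",
    "binomial_loglik",
    "SeparationError",
]

_Z90 = 1.6448536269514722  # two-sided 90% normal quantile


class SeparationError(ValueError):
    """Response pattern leaves the dose-response parameters unidentifiable."""


def binomial_loglik(
    b0: float, b1: float, doses: np.ndarray, n: np.ndarray, r: np.ndarray,
    link: str = "logit",
) -> float:
    """Grouped binomial log-likelihood (real-valued counts allowed).

    Constant binomial-coefficient terms are omitted; only the part that
    depends on (b0, b1) is returned.
    """
    eta = b0 + b1 * np.asarray(doses, dtype=float)
    if link == "logit":
        logp = -np.logaddexp(0.0, -eta)
        logq = -np.logaddexp(0.0, eta)
    elif link == "probit":
        from scipy.stats import norm

        logp = norm.logcdf(eta)
        logq = norm.logcdf(-eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    return float(np.sum(r * logp + (n - r) * logq))


def _grouped_counts(
    experiment: Experiment, use_effective: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group (dose, n, r), pooling any identical doses, dropping empty groups."""
    pooled: dict[float, list[float]] = {}
    for grp in experiment.groups:
        n, r = grp.effective_counts() if use_effective else (float(grp.n_raw), float(grp.r_raw))
        if n <= 0:
            continue
        entry = pooled.setdefault(grp.total_dose, [0.0, 0.0])
        entry[0] += n
        entry[1] += r
    doses = np.array(sorted(pooled))
    n = np.array([pooled[d][0] for d in doses])
    r = np.array([pooled[d][1] for d in doses])
    return doses, n, r


def _is_separated(doses: np.ndarray, n: np.ndarray, r: np.ndarray) -> bool:
    """True when every group responds at exactly 0% or 100% and both occur,
    with all 0% groups below all 100% groups."""
    frac = r / n
    pure0 = frac <= 0.0
    pure1 = frac >= 1.0
    if not np.all(pure0 | pure1) or not (pure0.any() and pure1.any()):
        return False
    return doses[pure0].max() < doses[pure1].min()


def fit_dose_response(
    experiment: Experiment,
    use_effective: bool = True,
    link: str = "logit",
    level: float = 0.90,
) -> DoseResponseFit:
    """Fit the dose-response curve of one experiment and derive TD50.

    Parameters
    ----------
    experiment
        Experiment with >= 2 informative dose groups.
    use_effective
        Use actuarially corrected counts where available (default); with
        complete follow-up these equal the raw counts and the switch has
        no effect.
    link
        ``"logit"`` (default) or ``"probit"``.  TD50 is -b0/b1 either way.
    level
        Confidence level for the Fieller limits on TD50.
    """
    doses, n, r = _grouped_counts(experiment, use_effective)
    if doses.size < 2:
        raise ValueError("need at least two dose groups with animals")
    if np.all(r <= 0) or np.all(r >= n):
        raise ValueError(
            "all-responder or all-nonresponder data: TD50 unidentifiable"
        )

    meta = dict(
        experiment_id=experiment.experiment_id,
        n_fractions=experiment.n_fractions,
        let_value=experiment.let_value,
        modality=experiment.modality,
    )

    if _is_separated(doses, n, r):
        frac = r / n
        d0 = doses[frac <= 0].max()
        d100 = doses[frac >= 1].min()
        return DoseResponseFit(
            b0=math.nan,
            b1=math.nan,
            cov=[[math.nan, math.nan], [math.nan, math.nan]],
            td50=(d0 + d100) / 2.0,
            se_td50=estimate_se_fallback(experiment, use_effective=use_effective),
            cl90=None,
            se_estimated=True,
            converged=True,
            loglik=0.0,  # separated data: likelihood supremum
            link=link,
            **meta,
        )

    links = {"logit": sm.families.links.Logit(), "probit": sm.families.links.Probit()}
    if link not in links:
        raise ValueError(f"unknown link {link!r}")
    endog = np.column_stack([r, n - r])
    exog = sm.add_constant(doses)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer counts trigger a DomainWarning
        model = sm.GLM(endog, exog, family=sm.families.Binomial(link=links[link]))
        res = model.fit(maxiter=200, tol=1e-10)

    b0, b1 = res.params
    cov = np.asarray(res.cov_params())
    td50 = -b0 / b1
    # Delta method on the ratio -b0/b1, keeping the b0-b1 correlation.
    grad = np.array([-1.0 / b1, b0 / b1**2])
    se_td50 = float(np.sqrt(grad @ cov @ grad))
    cl = fieller_cl(
        -b0, math.sqrt(cov[0, 0]), b1, math.sqrt(cov[1, 1]), -cov[0, 1], level
    )
    cl90: Optional[tuple[float, float]] = None if any(map(math.isinf, cl)) else cl

    # Quasi-separation: a nearly flat likelihood in the slope blows the
    # delta-method SE past any meaningful scale.  When the SE exceeds the
    # experiment's whole dose range the likelihood-based error is
    # unusable and the 25%-of-dose-gap estimate is reported instead.
    se_estimated = False
    dose_range = float(doses.max() - doses.min())
    if not math.isfinite(se_td50) or se_td50 > dose_range:
        try:
            se_td50 = estimate_se_fallback(experiment, use_effective=use_effective)
            se_estimated = True
            cl90 = None
        except ValueError:
            pass  # no 0%/100% levels either; keep the likelihood-based SE
    return DoseResponseFit(
        b0=float(b0),
        b1=float(b1),
        cov=cov.tolist(),
        td50=float(td50),
        se_td50=se_td50,
        cl90=cl90,
        se_estimated=se_estimated,
        converged=bool(res.converged),
        loglik=binomial_loglik(b0, b1, doses, n, r, link=link),
        link=link,
        **meta,
    )


def estimate_se_fallback(
    experiment: Experiment, use_effective: bool = False
) -> float:
    """SE of TD50 as 25% of the dose gap between the neighbouring 0% and
    100% observed response levels.

    Used when the likelihood-based SE is unavailable (complete
    separation).  If the 0%/100% levels overlap in dose, the two doses
    bracketing 50% response are used instead.
    """
    doses, n, r = _grouped_counts(experiment, use_effective)
    frac = r / n
    zeros = doses[frac <= 0.0]
    fulls = doses[frac >= 1.0]
    if zeros.size == 0 or fulls.size == 0:
        raise ValueError(
            "fallback SE needs both a 0% and a 100% observed response level"
        )
    gap = fulls.min() - zeros.max()
    if gap < 0:  # overlapping levels: bracket the 50% response instead
        crossing = [
            doses[i + 1] - doses[i]
            for i in range(doses.size - 1)
            if frac[i] < 0.5 <= frac[i + 1]
        ]
        if not crossing:
            raise ValueError("no adjacent doses bracketing 50% response")
        gap = crossing[0]
    if gap <= 0:
        raise ValueError("degenerate dose grid: zero gap between response levels")
    return 0.25 * float(gap)


def fieller_cl(
    num: float,
    se_num: float,
    den: float,
    se_den: float,
    cov: float = 0.0,
    level: float = 0.90,
) -> tuple[float, float]:
    """Fieller confidence limits for the ratio num/den.

    Exact normal-theory limits for a ratio of two (possibly correlated)
    normal estimates: the set of rho for which (num - rho*den) is within
    z standard errors of zero.  When g = (z se_den / den)^2 >= 1 the
    denominator is indistinguishable from zero at this level and the
    interval is unbounded; the sentinel ``(-inf, inf)`` is returned.
    """
    if den == 0:
        raise ValueError("denominator must be non-zero")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    ratio = num / den
    g = (z * se_den / den) ** 2
    if g >= 1.0:
        return (-math.inf, math.inf)
    v11, v22 = se_num**2, se_den**2
    inner = v11 - 2.0 * ratio * cov + ratio**2 * v22
    if v22 > 0:
        inner -= g * (v11 - cov**2 / v22)
    inner = max(inner, 0.0)
    half = (z / abs(den)) * math.sqrt(inner)
    centre = ratio - g * (cov / v22 if v22 > 0 else 0.0)
    low = (centre - half) / (1.0 - g)
    high = (centre + half) / (1.0 - g)
    return (low, high)
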