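"""Actuarial correction of censored toxicity data.

Not every animal in a late-toxicity study is observed for the full
follow-up horizon: some die of unrelated causes or are sacrificed before
the endpoint can develop.  Treating such animals as non-responders biases
the crude response rate downwards.  The effective-sample-size method
instead estimates the actuarial (product-limit) responder probability at
the horizon and replaces the raw treated/responder counts (n, r) by
values (n_eff, r_eff) whose binomial rate and variance match the
actuarial estimate and its Greenwood variance:

    n_eff = p (1 - p) / Var[p],    r_eff = n_eff * p.

With complete follow-up this reduces exactly to the raw counts; censoring
inflates the variance and hence shrinks n_eff, reflecting information
loss.  n_eff is capped at n_raw — the correction can only lose
information, never gain it.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .records import ActuarialEstimate, AnimalRecord, Experiment, LatencySummary

__all__ = [
    "actuarial_response",
    "effective_sample_size",
    "latency_summary",
    "apply_actuarial",
]

#: Maximum possible variance of a probability estimate (Bernoulli bound).
_VAR_CEILING = 0.25


def actuarial_response(
    times: Sequence[float], events: Sequence[int], horizon: float
) -> ActuarialEstimate:
    """Actuarial responder probability at the horizon.

    The survivor function S(t) for the toxicity event is estimated by the
    product-limit (Kaplan-Meier) method; responders are events at their
    onset day, everything else is censored at its last observation day.
    Returns p = 1 - S(horizon) with Greenwood's variance (which is the
    same for p and S).

    The ``immature_followup`` flag is set when the largest observation is
    a censoring time before the horizon, i.e. the estimate at the horizon
    is a carry-forward of incomplete information.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input: need at least one animal")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    n = times.size
    surv = 1.0
    greenwood_sum = 0.0  # sum of d / (n (n - d)) over event times
    for t in np.unique(times[(events == 1) & (times <= horizon)]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood_sum += d / (at_risk * (at_risk - d))
        # at_risk == d: survival hits zero, Greenwood variance degenerates to 0

    var = surv**2 * greenwood_sum if surv > 0 else 0.0
    var = min(var, _VAR_CEILING)
    last_censored = events[-1] == 0 and times[-1] < horizon
    return ActuarialEstimate(
        p_act=1.0 - surv,
        var_act=var,
        n_at_risk=n,
        immature_followup=bool(last_censored),
    )


def effective_sample_size(
    est: ActuarialEstimate, n_raw: int, r_raw: int
) -> tuple[float, float]:
    """Effective treated/responder counts matching the actuarial estimate.

    Degenerate rates (p = 0 or 1) and zero variance carry no censoring
    information beyond the raw counts, so those cases fall back to
    (n_raw, r_raw).
    """
    p, var = est.p_act, est.var_act
    if 0.0 < p < 1.0:
        if var <= 0.0:
            warnings.warn(
                "zero actuarial variance at intermediate response rate; "
                "falling back to raw counts",
                stacklevel=2,
            )
            return float(n_raw), float(r_raw)
        n_eff = p * (1.0 - p) / var
        n_eff = min(n_eff, float(n_raw))  # information can only be lost
        return n_eff, n_eff * p
    if p >= 1.0:
        return float(n_raw), float(n_raw)
    return float(n_raw), 0.0


def latency_summary(records: Sequence[AnimalRecord]) -> LatencySummary:
    """Min/mean/max latency over responders; censored animals are ignored."""
    lat = [a.time_days for a in records if a.event == 1 and not a.excluded]
    if not lat:
        return LatencySummary.empty()
    return LatencySummary(
        min_days=float(min(lat)),
        mean_days=float(np.mean(lat)),
        max_days=float(max(lat)),
        n_responders=len(lat),
    )


def apply_actuarial(experiment: Experiment) -> Experiment:
    """Fill each dose group's (n_eff, r_eff) in place and return the experiment."""
    for grp in experiment.groups:
        animals = grp.included_animals
        if not animals:
            grp.n_eff, grp.r_eff = 0.0, 0.0
            continue
        est = actuarial_response(
            [a.time_days for a in animals],
            [a.event for a in animals],
            experiment.horizon,
        )
        grp.n_eff, grp.r_eff = effective_sample_size(est, grp.n_raw, grp.r_raw)
        grp.immature_followup = est.immature_followup
    return experiment
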