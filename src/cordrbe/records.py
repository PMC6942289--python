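"""Domain types for the dose-response / RBE inference chain.

The hierarchy mirrors how a fractionated tolerance study is organised:
individual animals carry a dose assignment and a time-to-event outcome,
animals at the same total dose form a dose group, and the groups irradiated
at one LET position and fraction number form an experiment.  Downstream
result types (dose-response fit, LQ isoeffect fit, RBE estimate) carry
point estimates together with the covariance information needed for
error propagation on ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "AnimalRecord",
    "DoseGroup",
    "Experiment",
    "ActuarialEstimate",
    "LatencySummary",
    "DoseResponseFit",
    "ScheduleTD50",
    "LQFit",
    "RBEEstimate",
    "ComparisonResult",
]


@dataclass
class AnimalRecord:
    """One animal: dose assignment, outcome and exclusion status.

    ``event`` is 1 if the toxicity endpoint (paresis grade II, i.e.
    radiation-induced myelopathy) was observed within the follow-up
    horizon; otherwise the animal is censored at ``time_days`` (death or
    sacrifice without paresis, or end of follow-up).
    """

    animal_id: str
    experiment_id: str
    total_dose: float  # Gy, total physical dose over all fractions
    event: int  # 1 = responder (paresis grade II)
    time_days: float  # onset day for responders, last observation otherwise
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError(f"negative dose for animal {self.animal_id!r}")
        if self.time_days <= 0:
            raise ValueError(f"non-positive time for animal {self.animal_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1 for animal {self.animal_id!r}")
        if self.excluded and not self.exclusion_reason:
            raise ValueError(
                f"excluded animal {self.animal_id!r} must carry an exclusion reason"
            )


@dataclass
class DoseGroup:
    """Cohort of animals irradiated at one total dose level.

    ``n_eff``/``r_eff`` are the effective (actuarially corrected) treated
    and responder counts; they stay ``None`` until the actuarial stage
    fills them, in which case raw counts are used downstream.
    """

    total_dose: float
    animals: list[AnimalRecord] = field(default_factory=list)
    n_eff: Optional[float] = None
    r_eff: Optional[float] = None
    immature_followup: bool = False

    @property
    def included_animals(self) -> list[AnimalRecord]:
        return [a for a in self.animals if not a.excluded]

    @property
    def n_raw(self) -> int:
        """Number of analysable (non-excluded) animals."""
        return len(self.included_animals)

    @property
    def r_raw(self) -> int:
        """Number of responders among analysable animals."""
        return sum(a.event for a in self.included_animals)

    def effective_counts(self) -> tuple[float, float]:
        """(n, r) for fitting: effective counts if set, else raw."""
        if self.n_eff is not None and self.r_eff is not None:
            return float(self.n_eff), float(self.r_eff)
        return float(self.n_raw), float(self.r_raw)


@dataclass
class Experiment:
    """All dose groups at one (LET, fraction number) position.

    ``modality`` distinguishes the carbon-ion arms from the photon
    reference; LET is the dose-averaged value in keV/μm at the given
    water-equivalent depth in the spread-out Bragg peak.
    """

    experiment_id: str
    let_value: float  # keV/μm (0 for photons)
    depth_water_mm: float
    n_fractions: int
    groups: list[DoseGroup] = field(default_factory=list)
    horizon: float = 300.0  # days
    modality: str = "carbon"  # {"photon", "carbon"}

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")
        if self.modality not in ("photon", "carbon"):
            raise ValueError(f"unknown modality {self.modality!r}")
        doses = [g.total_dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError(
                f"experiment {self.experiment_id!r}: group doses must be "
                "strictly increasing"
            )

    @property
    def n_animals(self) -> int:
        """Total animals including excluded ones (audit count)."""
        return sum(len(g.animals) for g in self.groups)


@dataclass
class ActuarialEstimate:
    """Actuarial responder probability at the horizon with Greenwood variance."""

    p_act: float
    var_act: float
    n_at_risk: int
    immature_followup: bool = False


@dataclass
class LatencySummary:
    """Min/mean/max latency to paresis onset over responders only."""

    min_days: float
    mean_days: float
    max_days: float
    n_responders: int

    @classmethod
    def empty(cls) -> "LatencySummary":
        return cls(math.nan, math.nan, math.nan, 0)


@dataclass
class DoseResponseFit:
    """Logistic (or probit) dose-response fit with TD50 and its error.

    ``cov`` is the 2x2 covariance of (b0, b1) as nested lists.  When the
    likelihood is degenerate (complete separation) ``se_estimated`` is
    True and the SE comes from the 25%-of-dose-gap fallback rule.
    """

    b0: float
    b1: float
    cov: list  # 2x2 nested list
    td50: float
    se_td50: float
    cl90: Optional[tuple[float, float]]
    se_estimated: bool
    converged: bool
    loglik: float
    link: str = "logit"
    experiment_id: Optional[str] = None
    n_fractions: Optional[int] = None
    let_value: Optional[float] = None
    modality: Optional[str] = None


@dataclass
class ScheduleTD50:
    """One schedule's TD50 used as input to the LQ isoeffect fit."""

    n_fractions: int
    td50: float
    se_td50: float
    let_value: float = math.nan
    modality: str = "carbon"

    def __post_init__(self) -> None:
        if self.td50 <= 0 or self.se_td50 <= 0:
            raise ValueError("td50 and se_td50 must be positive")


@dataclass
class LQFit:
    """Joint LQ isoeffect fit across fraction numbers: α/β and BED50."""

    alpha_beta: float  # Gy
    se_alpha_beta: float
    bed50: float  # Gy
    se_bed50: float
    cov_ab_bed: float  # Gy^2
    cl90_ab: Optional[tuple[float, float]] = None
    cl90_bed: Optional[tuple[float, float]] = None
    converged: bool = True
    residual: float = 0.0
    let_value: float = math.nan
    modality: str = "carbon"


@dataclass
class RBEEstimate:
    """Ratio estimate (photon/ion) with propagated SE and Fieller CL.

    ``basis`` records whether the ratio is of TD50s (RBE at the tested
    schedule) or of BED50s (maximum RBE in the low-dose limit);
    ``n_fractions`` is None for the low-dose-limit estimate.
    """

    rbe: float
    se: float
    cl90: Optional[tuple[float, float]]
    basis: str  # {"td50_ratio", "bed50_ratio"}
    let_value: float = math.nan
    n_fractions: Optional[int] = None


@dataclass
class ComparisonResult:
    """Region-averaged model-vs-experiment RBE deviation statistics."""

    per_point_deviation_pct: list
    entrance_mean_pct: float
    entrance_sd_pct: float
    sobp_mean_pct: float
    sobp_sd_pct: float
    entrance_lets: list = field(default_factory=list)
    sobp_lets: list = field(default_factory=list)
    slope_ratio: Optional[float] = None
    slope_ratio_se: Optional[float] = None
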