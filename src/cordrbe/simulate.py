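"""Synthetic animal cohorts with the statistical structure the analysis assumes.

The raw animal data of fractionated spinal-cord tolerance studies are
rarely deposited, so every stage of the pipeline is exercised on
simulated cohorts instead.  Each animal responds with probability

    p(D) = 1 / (1 + exp(-b1 (D - TD50_true)))

at its assigned total dose; responders develop paresis at a lognormal
latency whose median decreases slightly with dose and LET, truncated to
the follow-up horizon; non-responders are censored at the horizon; and
each animal may independently drop out (death unrelated to the endpoint,
censored uniformly over the follow-up) with a small probability.

:func:`make_study_replica` reproduces a complete study design: six
carbon-ion experiments at LET 16-99 keV/μm with the published dose grids
and animal totals, plus a photon reference arm, all at six fractions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lq import invert_bed
from .records import AnimalRecord, DoseGroup, Experiment

__all__ = ["LatencyModel", "SimulationConfig", "simulate_experiment", "make_study_replica", "STUDY_DESIGN"]


@dataclass
class LatencyModel:
    """Lognormal onset-time model for responders.

    ``median_days`` is the latency median at zero dose and LET;
    ``dose_let_trend`` shrinks the log-median linearly in
    (total dose + LET), giving the slight decrease of latency with dose,
    LET and fraction number seen in this class of experiments.  Defaults
    put medians around 150-250 days inside a 300-day horizon.
    """

    median_days: float = 230.0
    sigma_log: float = 0.30
    dose_let_trend: float = 0.002  # per (Gy + keV/μm)

    def median_at(self, dose: float, let_value: float) -> float:
        return self.median_days * math.exp(-self.dose_let_trend * (dose + let_value))


@dataclass
class SimulationConfig:
    """Ground truth and design of one simulated experiment.

    The true TD50 may be given directly per (LET, fraction number), or
    derived from a true (BED50, alpha/beta) pair per LET through the LQ
    isoeffect relation.
    """

    true_td50: Optional[dict] = None  # {(let, n_fx): Gy}
    true_bed50: Optional[dict] = None  # {let: Gy}
    true_alpha_beta: Optional[dict] = None  # {let: Gy}
    slope_b1: float = 1.8  # per Gy, logistic steepness
    group_size: int = 5
    dose_levels: dict = field(default_factory=dict)  # {(let, n_fx): [Gy, ...]}
    group_sizes: dict = field(default_factory=dict)  # optional {(let, n_fx): [int, ...]}
    horizon: float = 300.0
    latency: LatencyModel = field(default_factory=LatencyModel)
    dropout_prob: float = 0.02
    seed: int = 0

    def lookup_td50(self, let_value: float, n_fractions: int) -> float:
        if self.true_td50 is not None:
            key = (let_value, n_fractions)
            if key in self.true_td50:
                return float(self.true_td50[key])
        if self.true_bed50 is not None and self.true_alpha_beta is not None:
            return invert_bed(
                self.true_bed50[let_value],
                self.true_alpha_beta[let_value],
                n_fractions,
            )
        raise KeyError(
            f"no true TD50 for LET {let_value}, {n_fractions} fractions"
        )


def _experiment_rng(seed: int, experiment_id: str) -> np.random.Generator:
    # One stream per experiment, keyed on (seed, id): adding experiments
    # leaves existing ones untouched.
    return np.random.default_rng([seed, zlib.crc32(experiment_id.encode())])


def simulate_experiment(
    config: SimulationConfig,
    let_value: float,
    n_fractions: int,
    experiment_id: Optional[str] = None,
    modality: str = "carbon",
    depth_water_mm: float = 0.0,
) -> Experiment:
    """Simulate one experiment (all dose groups) under ``config``.

    Deterministic for a given ``config.seed`` and experiment identity.
    """
    if config.dropout_prob < 0 or config.dropout_prob > 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    key = (let_value, n_fractions)
    if key not in config.dose_levels:
        raise KeyError(f"no dose levels configured for {key}")
    doses = list(config.dose_levels[key])
    if any(d < 0 for d in doses) or any(
        b <= a for a, b in zip(doses, doses[1:])
    ):
        raise ValueError("dose levels must be non-negative and strictly increasing")
    sizes = config.group_sizes.get(key, [config.group_size] * len(doses))
    if len(sizes) != len(doses):
        raise ValueError("group_sizes must match dose_levels in length")

    exp_id = experiment_id or f"{modality}_let{let_value:g}_fx{n_fractions}"
    rng = _experiment_rng(config.seed, exp_id)
    td50 = config.lookup_td50(let_value, n_fractions)
    b1 = config.slope_b1

    groups = []
    counter = 0
    for dose, size in zip(doses, sizes):
        animals = []
        for _ in range(size):
            counter += 1
            p = 1.0 / (1.0 + math.exp(-b1 * (dose - td50)))
            responder = rng.random() < p
            if responder:
                median = config.latency.median_at(dose, let_value)
                t = float(
                    rng.lognormal(math.log(median), config.latency.sigma_log)
                )
                # truncated resampling: onset must fall inside follow-up
                for _try in range(1000):
                    if t <= config.horizon:
                        break
                    t = float(
                        rng.lognormal(math.log(median), config.latency.sigma_log)
                    )
                t = min(t, config.horizon)
                event, time = 1, t
            else:
                event, time = 0, config.horizon
            if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
                t_drop = float(rng.uniform(0.0, config.horizon))
                if t_drop < time:  # dropout preempts a later onset
                    event, time = 0, t_drop
            animals.append(
                AnimalRecord(
                    animal_id=f"{exp_id}_a{counter:03d}",
                    experiment_id=exp_id,
                    total_dose=dose,
                    event=event,
                    time_days=max(time, 1e-6),
                    excluded=False,
                )
            )
        groups.append(DoseGroup(total_dose=dose, animals=animals))

    return Experiment(
        experiment_id=exp_id,
        let_value=let_value,
        depth_water_mm=depth_water_mm,
        n_fractions=n_fractions,
        groups=groups,
        horizon=config.horizon,
        modality=modality,
    )


#: Six-fraction carbon study design: per LET position the water-equivalent
#: depth [mm], the dose grid [Gy] and the total animal number, plus the
#: photon reference arm and the true TD50s used as simulation ground truth.
STUDY_DESIGN = {
    "carbon": {
        16.0: dict(depth=35.0, doses=[37, 38, 39, 40, 41, 45, 49], total=37, td50=39.1),
        21.0: dict(depth=65.0, doses=[30, 32, 34, 36, 38, 40], total=30, td50=33.8),
        36.0: dict(depth=80.0, doses=[25.5, 28.5, 31.5, 34.5], total=20, td50=28.7),
        45.0: dict(
            depth=100.0,
            doses=[21.67, 24.49, 26.38, 28.26, 30.14, 32.97],
            total=30,
            td50=26.9,
        ),
        66.0: dict(
            depth=120.0,
            doses=[14.5, 15.5, 16.5, 17.5, 18.5, 19.5, 20.5, 21.5, 22.5, 23.5, 24.5],
            total=55,
            td50=18.6,
        ),
        99.0: dict(depth=127.0, doses=[15, 16, 17, 18, 19, 20], total=32, td50=17.5),
    },
    # Photon reference arm (companion study design): TD50 57.0 Gy at 6 Fx.
    "photon": {
        0.0: dict(depth=0.0, doses=[50, 53, 56, 59, 62, 65], total=30, td50=57.0),
    },
}

_N_FRACTIONS = 6
_PHOTON_SLOPE = 0.6  # per Gy: photon curves are shallower in total dose


def _split_total(total: int, n_levels: int) -> list[int]:
    base, extra = divmod(total, n_levels)
    return [base + 1 if i < extra else base for i in range(n_levels)]


def make_study_replica(seed: int) -> tuple[list[Experiment], pd.DataFrame]:
    """Simulate the full six-fraction study: photon arm + six carbon LETs.

    Returns the experiments together with a ground-truth table (one row
    per experiment: modality, LET, fraction number, true TD50, slope)
    for parameter-recovery checks.
    """
    experiments: list[Experiment] = []
    truth_rows = []
    for modality, arms in STUDY_DESIGN.items():
        for let_value, design in arms.items():
            doses = [float(d) for d in design["doses"]]
            sizes = _split_total(design["total"], len(doses))
            slope = _PHOTON_SLOPE if modality == "photon" else 1.8
            config = SimulationConfig(
                true_td50={(let_value, _N_FRACTIONS): design["td50"]},
                slope_b1=slope,
                dose_levels={(let_value, _N_FRACTIONS): doses},
                group_sizes={(let_value, _N_FRACTIONS): sizes},
                dropout_prob=0.02,
                seed=seed,
            )
            exp = simulate_experiment(
                config,
                let_value,
                _N_FRACTIONS,
                modality=modality,
                depth_water_mm=design["depth"],
            )
            experiments.append(exp)
            truth_rows.append(
                {
                    "experiment_id": exp.experiment_id,
                    "modality": modality,
                    "let_kev_um": let_value,
                    "n_fractions": _N_FRACTIONS,
                    "true_td50_gy": design["td50"],
                    "slope_b1": slope,
                    "n_animals": sum(sizes),
                }
            )
    return experiments, pd.DataFrame(truth_rows)
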