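"""Shared fixtures: published summary values and small constructed cohorts."""

from __future__ import annotations

import pytest

from cordrbe.records import AnimalRecord, DoseGroup, Experiment

#: Published 6-fraction TD50 +/- SE [Gy] per dose-averaged LET [keV/um]
#: for the carbon arms, and the photon reference arm (LET key 0).
TD50_6FX = {
    0.0: (57.0, 2.0),
    16.0: (39.1, 0.4),
    21.0: (33.8, 0.6),
    36.0: (28.7, 1.5),
    45.0: (26.9, 0.5),
    66.0: (18.6, 0.4),
    99.0: (17.5, 0.3),
}

#: Published BED50 +/- SE [Gy] from the joint 1/2/6-fraction LQ analysis.
BED50 = {
    0.0: (244.9, 24.3),
    16.0: (76.3, 7.2),
    21.0: (53.3, 3.7),
    36.0: (39.5, 2.3),
    45.0: (36.4, 1.8),
    66.0: (20.3, 0.6),
    99.0: (19.0, 0.6),
}

#: Published alpha/beta +/- SE [Gy] per LET (photon under key 0).
ALPHA_BETA = {
    0.0: (2.8, 0.4),
    16.0: (6.9, 1.1),
    21.0: (9.8, 1.3),
    36.0: (14.6, 1.9),
    45.0: (12.8, 1.5),
    66.0: (44.3, 7.2),
    99.0: (30.8, 4.6),
}

ENTRANCE_LETS = [16.0, 21.0]
SOBP_LETS = [36.0, 45.0, 66.0, 99.0]


def make_group(dose: float, n: int, r: int, exp_id: str = "exp") -> DoseGroup:
    """Dose group with ``r`` responders (events at day 150) out of ``n``
    animals, the rest followed to day 300 without the endpoint."""
    animals = [
        AnimalRecord(
            animal_id=f"{exp_id}_d{dose:g}_{i}",
            experiment_id=exp_id,
            total_dose=dose,
            event=1 if i < r else 0,
            time_days=150.0 if i < r else 300.0,
        )
        for i in range(n)
    ]
    return DoseGroup(total_dose=dose, animals=animals)


def make_experiment(
    counts: list[tuple[float, int, int]],
    exp_id: str = "exp",
    n_fractions: int = 6,
    let_value: float = 99.0,
    modality: str = "carbon",
) -> Experiment:
    """Experiment from (dose, n, r) triples with complete follow-up."""
    return Experiment(
        experiment_id=exp_id,
        let_value=let_value,
        depth_water_mm=127.0,
        n_fractions=n_fractions,
        groups=[make_group(d, n, r, exp_id) for d, n, r in counts],
        modality=modality,
    )


@pytest.fixture
def symmetric_experiment() -> Experiment:
    """Two groups symmetric about 20 Gy: 1/5 at 18 Gy, 4/5 at 22 Gy."""
    return make_experiment([(18.0, 5, 1), (22.0, 5, 4)])


@pytest.fixture
def sobp36_experiment() -> Experiment:
    """The 36 keV/um-style dose grid: 0% at 25.5, partial at 28.5,
    100% at 31.5 and 34.5 Gy."""
    return make_experiment(
        [(25.5, 5, 0), (28.5, 5, 2), (31.5, 5, 5), (34.5, 5, 5)],
        let_value=36.0,
    )
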