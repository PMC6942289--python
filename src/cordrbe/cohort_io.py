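"""Reading and writing cohort CSV files and result JSON.

The cohort dialect is a flat UTF-8 CSV with one row per animal; rows are
grouped into experiments by ``experiment_id`` and into dose groups by the
exact printed total dose (no tolerance binning — studies of this design
use distinct listed dose levels).  Excluded animals (intercurrent tumour,
death unrelated to the endpoint) are kept in the file model for audit but
dropped from the analysable counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .records import (
    AnimalRecord,
    ComparisonResult,
    DoseGroup,
    DoseResponseFit,
    Experiment,
    LatencySummary,
    LQFit,
    RBEEstimate,
    ScheduleTD50,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
    "read_td50_table",
    "read_rbe_table",
]

REQUIRED_COLUMNS = [
    "experiment_id",
    "let_kev_um",
    "depth_mm",
    "n_fractions",
    "total_dose_gy",
    "animal_id",
    "event",
    "time_days",
    "excluded",
    "exclusion_reason",
]

#: Optional column; defaults to "carbon" when absent.
MODALITY_COLUMN = "modality"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class CohortValidationError(ValueError):
    """A row fails validation (negative dose/time, bad event flag, ...)."""


def read_cohort(path: Union[str, Path], horizon: float = 300.0) -> list[Experiment]:
    """Read an animal-level cohort CSV and assemble the experiment hierarchy.

    Parameters
    ----------
    path
        CSV file with the columns in :data:`REQUIRED_COLUMNS` (plus an
        optional ``modality`` column).
    horizon
        Follow-up horizon in days attached to each experiment.

    Returns
    -------
    list of :class:`~cordrbe.records.Experiment`, ordered by first
    appearance in the file, with dose groups in increasing dose order and
    excluded animals flagged but retained.
    """
    df = pd.read_csv(
        path, dtype={"exclusion_reason": "string"}, float_precision="round_trip"
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")

    experiments: list[Experiment] = []
    for exp_id in df["experiment_id"].drop_duplicates():
        sub = df[df["experiment_id"] == exp_id]
        groups: dict[float, DoseGroup] = {}
        for idx, row in sub.iterrows():
            dose = float(row["total_dose_gy"])
            time = float(row["time_days"])
            if dose < 0:
                raise CohortValidationError(f"row {idx}: negative dose {dose}")
            if time <= 0:
                raise CohortValidationError(f"row {idx}: non-positive time {time}")
            reason = row["exclusion_reason"]
            reason = None if pd.isna(reason) else str(reason)
            try:
                rec = AnimalRecord(
                    animal_id=str(row["animal_id"]),
                    experiment_id=str(exp_id),
                    total_dose=dose,
                    event=int(row["event"]),
                    time_days=time,
                    excluded=bool(int(row["excluded"])),
                    exclusion_reason=reason,
                )
            except ValueError as exc:
                raise CohortValidationError(f"row {idx}: {exc}") from exc
            groups.setdefault(dose, DoseGroup(total_dose=dose)).animals.append(rec)

        first = sub.iloc[0]
        modality = (
            str(first[MODALITY_COLUMN])
            if MODALITY_COLUMN in sub.columns and not pd.isna(first[MODALITY_COLUMN])
            else "carbon"
        )
        experiments.append(
            Experiment(
                experiment_id=str(exp_id),
                let_value=float(first["let_kev_um"]),
                depth_water_mm=float(first["depth_mm"]),
                n_fractions=int(first["n_fractions"]),
                groups=[groups[d] for d in sorted(groups)],
                horizon=horizon,
                modality=modality,
            )
        )
    return experiments


def write_cohort(experiments: list[Experiment], path: Union[str, Path]) -> None:
    """Write experiments back to the flat cohort CSV dialect."""
    rows = []
    for exp in experiments:
        for grp in exp.groups:
            for a in grp.animals:
                rows.append(
                    {
                        "experiment_id": exp.experiment_id,
                        "let_kev_um": exp.let_value,
                        "depth_mm": exp.depth_water_mm,
                        "n_fractions": exp.n_fractions,
                        "modality": exp.modality,
                        "total_dose_gy": a.total_dose,
                        "animal_id": a.animal_id,
                        "event": a.event,
                        "time_days": a.time_days,
                        "excluded": int(a.excluded),
                        "exclusion_reason": a.exclusion_reason or "",
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


_RESULT_TYPES = {
    cls.__name__: cls
    for cls in (
        DoseResponseFit,
        LQFit,
        RBEEstimate,
        ScheduleTD50,
        LatencySummary,
        ComparisonResult,
    )
}


def _jsonable(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        value = value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    if isinstance(value, float) and not math.isfinite(value):
        return None
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def _round2(value: Any) -> Any:
    if isinstance(value, (int, float)) and value is not None and math.isfinite(value):
        return round(value, 2)
    if isinstance(value, (list, tuple)):
        return [_round2(v) for v in value]
    return value


#: Display-precision fields per result type (2 decimals, as in the study tables).
_ROUNDED_FIELDS = {
    "DoseResponseFit": ("td50", "se_td50", "cl90"),
    "LQFit": ("alpha_beta", "se_alpha_beta", "bed50", "se_bed50", "cl90_ab", "cl90_bed"),
    "RBEEstimate": ("rbe", "se", "cl90"),
    "ScheduleTD50": ("td50", "se_td50"),
    "LatencySummary": ("min_days", "mean_days", "max_days"),
    "ComparisonResult": ("entrance_mean_pct", "entrance_sd_pct", "sobp_mean_pct", "sobp_sd_pct"),
}


def write_results(result: Any, path: Union[str, Path]) -> None:
    """Serialize a result dataclass (or list/dict of them) to JSON.

    The JSON carries the full-precision fields plus a ``rounded`` block at
    display precision (2 decimals).  Non-finite numbers serialize as null;
    a null ``se_td50`` is accompanied by ``"se_estimated": false`` in the
    full-precision block so the consumer can tell "not estimable" from
    "estimated by the fallback rule".
    """
    payload = _encode(result)
    Path(path).write_text(json.dumps(payload, indent=2))


def _encode(result: Any) -> Any:
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        name = type(result).__name__
        data = _jsonable(dataclasses.asdict(result))
        if name == "DoseResponseFit" and data.get("se_td50") is None:
            data["se_estimated"] = False
        rounded = {
            k: _round2(data[k])
            for k in _ROUNDED_FIELDS.get(name, ())
            if data.get(k) is not None
        }
        if name == "RBEEstimate" and data.get("cl90") is not None:
            rounded["cl90_low"], rounded["cl90_high"] = rounded.pop("cl90")
        return {"type": name, "data": data, "rounded": rounded}
    if isinstance(result, dict):
        return {k: _encode(v) for k, v in result.items()}
    if isinstance(result, (list, tuple)):
        return [_encode(v) for v in result]
    return _jsonable(result)


def read_results(path: Union[str, Path]) -> Any:
    """Inverse of :func:`write_results` for single objects and containers."""
    return _decode(json.loads(Path(path).read_text()))


def _decode(payload: Any) -> Any:
    if isinstance(payload, dict) and "type" in payload and "data" in payload:
        cls = _RESULT_TYPES[payload["type"]]
        data = dict(payload["data"])
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if v is None and f.name in ("td50", "se_td50", "b0", "b1", "loglik"):
                v = math.nan
            if isinstance(v, list) and f.name in ("cl90", "cl90_ab", "cl90_bed"):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)
    if isinstance(payload, dict):
        return {k: _decode(v) for k, v in payload.items()}
    if isinstance(payload, list):
        return [_decode(v) for v in payload]
    return payload


def read_td50_table(path: Union[str, Path]) -> list[ScheduleTD50]:
    """Read a TD50-per-schedule table.

    Columns: ``modality, let_kev_um, n_fractions, td50_gy, se_gy``.
    """
    df = pd.read_csv(path)
    for col in ("modality", "let_kev_um", "n_fractions", "td50_gy", "se_gy"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return [
        ScheduleTD50(
            n_fractions=int(r.n_fractions),
            td50=float(r.td50_gy),
            se_td50=float(r.se_gy),
            let_value=float(r.let_kev_um),
            modality=str(r.modality),
        )
        for r in df.itertuples()
    ]


def read_rbe_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read an RBE table (experimental or model-predicted).

    Columns: ``let_kev_um, n_fractions, rbe`` plus optional ``depth_mm``,
    ``se`` and ``source``.  ``n_fractions`` may be the string ``inf`` for
    the low-dose-limit (maximum RBE) rows.
    """
    df = pd.read_csv(path)
    for col in ("let_kev_um", "n_fractions", "rbe"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df.copy()
    df["n_fractions"] = df["n_fractions"].astype(float)  # inf-capable
    return df
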