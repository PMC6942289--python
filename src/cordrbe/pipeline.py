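"""End-to-end orchestration: cohort -> actuarial -> fits -> RBE -> comparison.

Every stage is a thin call into the corresponding module; the pipeline
only sequences them, wraps stage failures with the stage name, and
writes the result JSON files plus a run log echoing the configuration.
"""

from __future__ import annotations

import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .actuarial import apply_actuarial
from .cohort_io import read_cohort, read_rbe_table, write_results
from .compare import compare_tables
from .dose_response import fit_dose_response
from .lq import fit_lq
from .rbe import compute_rbe
from .records import DoseResponseFit, ScheduleTD50

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


@dataclass
class PipelineConfig:
    cohort_path: str
    out_dir: str
    model_table_path: Optional[str] = None
    link: str = "logit"
    use_actuarial: bool = True
    level: float = 0.90
    entrance_lets: Sequence[float] = (16.0, 21.0)
    sobp_lets: Sequence[float] = (36.0, 45.0, 66.0, 99.0)
    aggregate_over: str = "let"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if set(self.entrance_lets) & set(self.sobp_lets):
            raise ValueError("entrance and SOBP regions must be disjoint")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages; returns {stage: results} and writes JSON.

    Deterministic given the input files and config.  Raises
    :class:`StageError` naming the first failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        experiments = read_cohort(config.cohort_path)
    except Exception as exc:
        raise StageError("cohort_io", exc) from exc

    if config.use_actuarial:
        try:
            for exp in experiments:
                apply_actuarial(exp)
        except Exception as exc:
            raise StageError("actuarial", exc) from exc

    try:
        fits: dict[str, DoseResponseFit] = {}
        for exp in experiments:
            fits[exp.experiment_id] = fit_dose_response(
                exp,
                use_effective=config.use_actuarial,
                link=config.link,
                level=config.level,
            )
        write_results(fits, out / "fit.json")
        bundle["fits"] = fits
    except Exception as exc:
        raise StageError("dose_response", exc) from exc

    # RBE per carbon experiment against the photon arm at equal Fx
    try:
        photon_fits = {
            f.n_fractions: f for f in fits.values() if f.modality == "photon"
        }
        rbes = {}
        for f in fits.values():
            if f.modality != "carbon" or f.n_fractions not in photon_fits:
                continue
            ph = photon_fits[f.n_fractions]
            rbes[f.experiment_id] = compute_rbe(
                (ph.td50, ph.se_td50),
                (f.td50, f.se_td50),
                level=config.level,
                let_value=f.let_value if f.let_value is not None else math.nan,
                n_fractions=f.n_fractions,
            )
        write_results(rbes, out / "rbe.json")
        bundle["rbe"] = rbes
    except Exception as exc:
        raise StageError("rbe", exc) from exc

    # Joint LQ fit per LET when several fraction numbers are present
    try:
        by_let: dict[tuple[str, float], list[ScheduleTD50]] = {}
        for f in fits.values():
            key = (f.modality or "carbon", f.let_value if f.let_value is not None else math.nan)
            by_let.setdefault(key, []).append(
                ScheduleTD50(
                    n_fractions=f.n_fractions,
                    td50=f.td50,
                    se_td50=f.se_td50,
                    let_value=key[1],
                    modality=key[0],
                )
            )
        lq_fits = {
            f"{mod}_let{let:g}": fit_lq(scheds, level=config.level)
            for (mod, let), scheds in by_let.items()
            if len({s.n_fractions for s in scheds}) >= 2
        }
        write_results(lq_fits, out / "lq.json")
        bundle["lq"] = lq_fits
    except Exception as exc:
        raise StageError("lq_analysis", exc) from exc

    if config.model_table_path is not None:
        try:
            model = read_rbe_table(config.model_table_path)
            exp_rows = [
                {
                    "let_kev_um": r.let_value,
                    "n_fractions": float(r.n_fractions or 0),
                    "rbe": r.rbe,
                }
                for r in bundle["rbe"].values()
            ]
            import pandas as pd

            cmp = compare_tables(
                model,
                pd.DataFrame(exp_rows),
                entrance_lets=config.entrance_lets,
                sobp_lets=config.sobp_lets,
                aggregate_over=config.aggregate_over,
            )
            write_results(cmp, out / "cmp.json")
            bundle["comparison"] = cmp
        except Exception as exc:
            raise StageError("model_comparison", exc) from exc

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle
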