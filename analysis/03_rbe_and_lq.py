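#!/usr/bin/env python
"""RBE per LET position, joint LQ isoeffect fits, and maximum RBE.

Reads the fitted TD50 table (from 02_fit_dose_response.py) and computes
the RBE at six fractions as the photon/carbon TD50 ratio with propagated
SE and Fieller 90% limits.  Single- and split-dose TD50s are then added
as synthetic companion schedules — generated from the published
(BED50, alpha/beta) values per LET, since those studies' raw data are
separate publications — and the joint LQ fit recovers alpha/beta and
BED50 per LET, from which the maximum RBE follows as the BED50 ratio.
"""

import argparse
from pathlib import Path

import pandas as pd

from cordrbe.cohort_io import write_results
from cordrbe.lq import fit_lq, invert_bed
from cordrbe.rbe import compute_rbe, compute_rbe_max
from cordrbe.records import ScheduleTD50

RESULTS = Path(__file__).resolve().parents[1] / "results"

#: Published joint-fit values used as the generating truth for the
#: synthetic 1- and 2-fraction companion schedules: BED50 [Gy] and
#: alpha/beta [Gy] per LET (photon arm under key 0).
BED_AB_TRUTH = {
    0.0: (244.9, 2.8),
    16.0: (76.3, 6.9),
    21.0: (53.3, 9.8),
    36.0: (39.5, 14.6),
    45.0: (36.4, 12.8),
    66.0: (20.3, 44.3),
    99.0: (19.0, 30.8),
}


def main(seed: int = 1) -> None:
    td50s = pd.read_csv(RESULTS / "td50_table.csv")
    photon = td50s[td50s.modality == "photon"].iloc[0]

    rbes = {}
    print("RBE at 6 fractions (photon/carbon TD50 ratio):")
    for row in td50s[td50s.modality == "carbon"].itertuples():
        est = compute_rbe(
            (photon.td50_gy, photon.se_gy),
            (row.td50_gy, row.se_gy),
            let_value=row.let_kev_um,
            n_fractions=6,
        )
        rbes[f"let{row.let_kev_um:g}"] = est
        print(
            f"  LET {row.let_kev_um:5.1f}: RBE {est.rbe:.2f} ± {est.se:.2f} "
            f"(90% CL {est.cl90[0]:.2f}-{est.cl90[1]:.2f})"
        )
    write_results(rbes, RESULTS / "rbe.json")

    # Joint LQ fits: fitted 6-Fx TD50 + synthetic 1/2-Fx companion TD50s
    # (3% relative SE, a typical reported precision for those studies).
    lq_fits, rbe_max = {}, {}
    print("\nJoint LQ fits (6-Fx fitted TD50 + synthetic 1/2-Fx schedules):")
    for row in td50s.itertuples():
        let = row.let_kev_um if row.modality == "carbon" else 0.0
        bed, ab = BED_AB_TRUTH[let]
        schedules = [
            ScheduleTD50(n, invert_bed(bed, ab, n), 0.03 * invert_bed(bed, ab, n),
                         let_value=let, modality=row.modality)
            for n in (1, 2)
        ]
        schedules.append(
            ScheduleTD50(6, row.td50_gy, row.se_gy, let_value=let,
                         modality=row.modality)
        )
        fit = fit_lq(schedules)
        lq_fits[f"{row.modality}_let{let:g}"] = fit
        print(
            f"  {row.modality:6s} LET {let:5.1f}: alpha/beta "
            f"{fit.alpha_beta:5.1f} ± {fit.se_alpha_beta:4.1f} Gy, "
            f"BED50 {fit.bed50:6.1f} ± {fit.se_bed50:4.1f} Gy"
        )

    print("\nMaximum RBE (BED50 ratio, low-dose limit):")
    ph_fit = lq_fits["photon_let0"]
    for key, fit in lq_fits.items():
        if fit.modality != "carbon":
            continue
        est = compute_rbe_max(ph_fit, fit)
        rbe_max[key] = est
        print(f"  LET {fit.let_value:5.1f}: RBE_max {est.rbe:5.2f} ± {est.se:4.2f}")

    write_results({"lq": lq_fits, "rbe_max": rbe_max}, RESULTS / "lq_rbe_max.json")
    print(f"\nwrote {RESULTS/'rbe.json'} and {RESULTS/'lq_rbe_max.json'}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    main(**vars(p.parse_args()))
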