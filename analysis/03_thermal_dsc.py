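#!/usr/bin/env python
"""Thermal stability: melting-curve fits and DSC endotherm analysis.

Scenario data use the published thermal midpoints (CD, pH 7.3) and DSC
results: a PsTRXf-like reversible two-state endotherm at 68.5 degC with
dH_cal = 61.6 kcal/mol, and a PsTRXh2-like sequential three-state
endotherm with Tmax near 66.3 degC. The re-heating scan of PsTRXh2 is
emulated by a quarter-amplitude endotherm (about 70% of the protein
fails to refold after the first scan).

Finding: fitted Tm values are invariant (<0.1 degC) to whether dCp is
fixed at 1.2 kcal/mol/K or floated; the two-state endotherm gives
dH_vH/dH_cal ~ 1.0 (a clean two-state transition); the rescan scenario
reproduces a four-fold lower calorimetric enthalpy at unchanged Tmax.

Writes results/thermal_dsc.csv.
"""

from pathlib import Path

import pandas as pd

from trxstab import (
    DSCParams,
    DSCTransition,
    NoiseSpec,
    ThermalParams,
    fit_dsc,
    fit_thermal,
    gen_dsc_endotherm,
    gen_thermal_curve,
)
from trxstab.tables import TM_CD_PH73

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20110222


def main() -> None:
    rows = []
    for protein, tm in TM_CD_PH73.items():
        truth = ThermalParams(tm, 110.0, 1.2, 1.0, -0.002, 0.1, 0.001)
        curve = gen_thermal_curve(truth, noise=NoiseSpec(sigma=0.02, seed=SEED), probe="cd")
        fixed = fit_thermal(curve, dcp_mode="fixed", seed=SEED)
        free = fit_thermal(curve, dcp_mode="free", seed=SEED)
        rows.append(
            {
                "protein": protein,
                "tm_true_C": tm,
                "tm_fixed_dcp_C": round(fixed["tm_C"], 2),
                "tm_free_dcp_C": round(free["tm_C"], 2),
                "dcp_invariance_C": round(abs(fixed["tm_C"] - free["tm_C"]), 3),
                "dS_kcal_mol_K": round(fixed.meta["dS_kcal_mol_K"], 3),
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "thermal_dsc.csv", index=False)
    print(frame.to_string(index=False))

    # PsTRXf-like reversible two-state endotherm
    two = fit_dsc(gen_dsc_endotherm(DSCParams([DSCTransition(68.5, 61.6)], "two_state")),
                  "two_state")
    print(f"\nTwo-state endotherm: Tm = {two['tm1_C']:.1f} degC, "
          f"dH_vH = {two['dH1']:.1f}, dH_cal = {two.meta['dH_cal_kcal_mol']:.1f} kcal/mol, "
          f"ratio = {two.meta['ratio_vH_over_cal']:.2f}")

    # PsTRXh2-like sequential three-state endotherm and its rescan
    three_truth = DSCParams([DSCTransition(62.0, 70.0), DSCTransition(68.0, 85.0)],
                            "sequential_three_state")
    three = fit_dsc(gen_dsc_endotherm(three_truth), "sequential_three_state")
    print(f"Three-state endotherm: Tm1 = {min(three['tm1_C'], three['tm2_C']):.1f}, "
          f"Tm2 = {max(three['tm1_C'], three['tm2_C']):.1f} degC, "
          f"Tmax = {three.meta['tmax_C']:.1f} degC")

    rescan = fit_dsc(
        gen_dsc_endotherm(DSCParams(three_truth.transitions, "sequential_three_state", scale=0.25)),
        "sequential_three_state",
    )
    print(f"Re-heating scan: dH_cal drops {three.meta['dH_cal_kcal_mol'] / rescan.meta['dH_cal_kcal_mol']:.1f}-fold "
          f"while Tmax moves {abs(rescan.meta['tmax_C'] - three.meta['tmax_C']):.2f} degC "
          "- partial irreversibility at preserved transition temperatures.")


if __name__ == "__main__":
    main()
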