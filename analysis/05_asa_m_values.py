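#!/usr/bin/env python
"""Surface-area bookkeeping and theoretical m-values.

Computes the per-polarity delta-ASA (extended minus folded state) for
each thioredoxin from the structure-derived surface-area tables, then
predicts GdmCl m-values with the Myers/Pace regression
m = 0.859 + 2.2e-4 * delta_ASA_total.

Finding: theoretical m-values cluster tightly at 3.70-3.77 kcal/mol/M
for all three proteins - substantially larger than every experimentally
fitted m (1.4-2.6 by spectroscopy), consistent with denatured states
that retain residual structure and expose less new surface than a fully
extended chain. The polar delta-ASA runs opposite to the stability
ranking (most stable protein, smallest polar delta-ASA).

Writes results/asa_m_values.csv.
"""

from pathlib import Path

import pandas as pd

from trxstab import lem_consistency, predict_m_value
from trxstab.tables import ASA_TABLES, CHEM_DENATURATION

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for protein, table in ASA_TABLES.items():
        pred = predict_m_value(table)
        m_exp = CHEM_DENATURATION[protein]["fluorescence"][0]
        rows.append(
            {
                "protein": protein,
                "delta_asa_nonpolar_A2": round(pred.delta_asa_nonpolar, 1),
                "delta_asa_polar_A2": round(pred.delta_asa_polar, 1),
                "delta_asa_total_A2": round(pred.delta_asa_total, 1),
                "m_theory_kcal_mol_M": round(pred.m_theory, 2),
                "m_exp_fluorescence": m_exp,
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "asa_m_values.csv", index=False)
    print(frame.to_string(index=False))

    dev = lem_consistency(2.3, 3.19, 7.3)
    print(f"\nLEM self-consistency for PsTRXh1: m*U50 deviates {dev:.1%} "
          "from the reported 7.3 kcal/mol.")
    print("Theoretical m-values (3.6-3.8) exceed all fitted ones: the "
          "GdmCl-denatured states are not fully extended chains.")


if __name__ == "__main__":
    main()
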