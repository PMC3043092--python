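"""Published reference inputs for the three pea thioredoxins.

These are the measured/printed quantities the analysis consumes as
inputs: sequence-derived biophysical parameters, NMR relaxation times,
the SEC column constants and calibration line, the chemical-denaturation
fit parameters, the DSC results and the per-protein ASA tables. The raw
instrument traces behind them are not deposited anywhere, so fitting
stages are exercised on synthetic data generated with these values as
ground truth (see :mod:`trxstab.synth`).
"""

from __future__ import annotations

import pandas as pd

from .asa import ASATable
from .hydro import CalibrationStandard, SECCalibration, SECColumn

PROTEINS = ("PsTRXh1", "PsTRXh2", "PsTRXf")

#: Sequence-derived parameters (molecular weight kDa, residue count).
BIOPHYSICAL = pd.DataFrame(
    {
        "mw_kda": [13.1, 13.0, 12.1],
        "n_residues": [120, 118, 109],
        "theoretical_rs_A": [19.0, 19.0, 18.0],
        "theoretical_r0_A": [15.6, 15.5, 15.2],
    },
    index=list(PROTEINS),
)

#: NMR and SEC hydrodynamic measurements at 25 degC, pH 7.0.
HYDRODYNAMICS = pd.DataFrame(
    {
        "t2_ms": [30.0, 30.5, 28.7],
        "tau_c_ns": [6.7, 6.5, 6.9],
        "mw_nmr_kda": [13.4, 13.1, 13.7],
        "ve_ml": [13.3, 12.8, 13.5],
        "rs_exp_A": [14.0, 16.0, 14.0],
    },
    index=list(PROTEINS),
)

#: Superdex 75 column constants (void and internal volumes, ml).
COLUMN = SECColumn(vo_ml=7.88, vi_ml=18.72)

#: Published calibration line Rs = 1.69 + 26.7 * erfc^-1(sigma).
CALIBRATION = SECCalibration(a=1.69, b=26.7, stderr_a=1.79, stderr_b=1.56)

#: Gel-filtration standards (Stokes radii, angstrom).
STANDARD_RADII = {
    "ribonuclease A": 16.4,
    "chymotrypsinogen": 20.9,
    "ovalbumin": 30.5,
    "bovine serum albumin": 35.5,
}

#: GdmCl denaturation parameters at pH 7.0, 25 degC:
#: (m kcal/mol/M, [GdmCl]50% M) per probe.
CHEM_DENATURATION = {
    "PsTRXh1": {"fluorescence": (2.3, 3.19), "cd": (2.3, 3.16), "sec": (11.0, 2.76)},
    "PsTRXh2": {"fluorescence": (2.6, 2.62), "cd": (1.4, 1.56), "sec": (6.0, 1.80)},
    "PsTRXf": {"fluorescence": (1.9, 2.00), "cd": (1.9, 1.8)},
}

#: Averaged m-value for PsTRXh1 over pH 5-9 (fluorescence+CD) and the
#: reported unfolding free energy in water.
PSTRXH1_M_AVERAGE = 2.3
PSTRXH1_DG_WATER = 7.3

#: Thermal midpoints (degC) by CD at pH 7.3.
TM_CD_PH73 = {"PsTRXh1": 77.0, "PsTRXh2": 66.5, "PsTRXf": 71.2}

#: DSC results at pH 7.3.
DSC_RESULTS = {
    "PsTRXh2": {"model": "sequential_three_state", "tmax_C": 66.3, "rescan_tmax_C": 66.6},
    "PsTRXf": {"model": "two_state", "tm_C": 68.5, "dH_cal": 61.6, "dH_vH": 63.2},
}

#: pKa values resolved from the pH titrations.
PKA_VALUES = {
    "PsTRXh1": {"fluorescence_avg_wavelength": 6.3, "ans_bell": (8.1, 10.4)},
    "PsTRXh2": {"cd_acidic": 5.1, "cd_basic": 8.6},
    "PsTRXf": {"fluorescence_avg_wavelength": 4.31},
}

#: Structure-derived ASA tables (angstrom^2) and main-chain H-bond counts.
ASA_TABLES = {
    "PsTRXh1": ASATable(
        protein="PsTRXh1",
        folded_nonpolar=3774.1,
        folded_polar=2934.5,
        extended_nonpolar=12360.7,
        extended_polar=7593.4,
        hbond_count=80,
    ),
    "PsTRXh2": ASATable(
        protein="PsTRXh2",
        folded_nonpolar=3950.6,
        folded_polar=2521.9,
        extended_nonpolar=12250.1,
        extended_polar=7407.6,
        hbond_count=81,
    ),
    "PsTRXf": ASATable(
        protein="PsTRXf",
        folded_nonpolar=3988.1,
        folded_polar=2303.0,
        extended_nonpolar=12249.8,
        extended_polar=6965.7,
        hbond_count=77,
    ),
}

#: Published per-polarity delta-ASA rows (angstrom^2), for cross-checks.
DELTA_ASA_PUBLISHED = {
    "PsTRXh1": {"nonpolar": 8586.6, "polar": 4658.9},
    "PsTRXh2": {"nonpolar": 8299.5, "polar": 4885.7},
    "PsTRXf": {"nonpolar": 8261.7, "polar": 4662.7},
}


def calibration_standards(
    cal: SECCalibration = CALIBRATION, column: SECColumn = COLUMN
) -> list[CalibrationStandard]:
    """The four standards with noiseless elution volumes implied by the
    published calibration line (their measured Ve are not published)."""
    from .hydro import elution_volume

    return [
        CalibrationStandard(name, rs, elution_volume(rs, cal, column))
        for name, rs in STANDARD_RADII.items()
    ]
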