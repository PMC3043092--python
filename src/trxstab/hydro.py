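"""Hydrodynamics: SEC column calibration and theoretical/NMR size estimators.

Size-exclusion chromatography (Ackers' treatment): the partition
coefficient of a macromolecule eluting at volume Ve from a column with
void volume Vo and internal volume Vi is

    sigma = (Ve - Vo) / Vi,                                  (dimensionless)

and the Stokes radius follows the linear calibration

    Rs = a + b * erfc^-1(sigma)                              [angstrom],

where erfc^-1 is the inverse of the standard complementary error
function erfc(x) = 1 - erf(x). Sigma outside (0, 1) signals
protein-column interaction (late elution at acidic pH) rather than
ideal partitioning and is flagged, not silently accepted.

Theoretical estimators:

* anhydrous sphere radius  r0 = (3 M vbar / (4 pi N_Av))^(1/3)
* folded-chain scaling     Rs = 4.75 * N^0.29  (N residues)
* NMR rotational correlation time tau_c ~ 1/(5 T2) (10% inherent
  uncertainty) and the linear mass estimate MW = k * tau_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcinv

from .constants import AVOGADRO, DEFAULT_VBAR

__all__ = [
    "SECColumn",
    "CalibrationStandard",
    "SECCalibration",
    "partition_coefficient",
    "fit_sec_calibration",
    "stokes_radius",
    "elution_volume",
    "sphere_radius",
    "wilkins_radius",
    "correlation_time",
    "mw_from_correlation_time",
]

#: Inherent relative uncertainty of the 1/(5 T2) correlation-time rule.
TAU_C_RELATIVE_UNCERTAINTY = 0.10


@dataclass
class SECColumn:
    vo_ml: float
    vi_ml: float

    def __post_init__(self) -> None:
        if self.vo_ml <= 0 or self.vi_ml <= 0:
            raise ValueError("column volumes must be positive")

    @property
    def total_ml(self) -> float:
        return self.vo_ml + self.vi_ml


@dataclass
class CalibrationStandard:
    name: str
    rs_A: float
    ve_ml: float


@dataclass
class SECCalibration:
    """Rs = a + b * erfc^-1(sigma); b > 0 for a physically sensible column."""

    a: float
    b: float
    stderr_a: float | None = None
    stderr_b: float | None = None
    residuals: dict = field(default_factory=dict)


def partition_coefficient(ve_ml: float, column: SECColumn) -> float:
    """sigma = (Ve - Vo)/Vi; warns above 1 (column interaction)."""
    if ve_ml < column.vo_ml:
        raise ValueError(f"Ve = {ve_ml} ml elutes before the void volume")
    sigma = (ve_ml - column.vo_ml) / column.vi_ml
    if sigma > 1:
        warnings.warn(
            f"sigma = {sigma:.3f} > 1: elution beyond the total column "
            "volume suggests protein-column interaction",
            stacklevel=2,
        )
    return float(sigma)


def fit_sec_calibration(
    standards: list[CalibrationStandard], column: SECColumn
) -> SECCalibration:
    """Linear least-squares calibration of Rs against erfc^-1(sigma).

    Standards whose partition coefficient falls outside (0, 1) are
    excluded with a warning; at least three usable standards with
    distinct sigma are required.
    """
    usable: list[tuple[CalibrationStandard, float]] = []
    for st in standards:
        sigma = (st.ve_ml - column.vo_ml) / column.vi_ml
        if not 0.0 < sigma < 1.0:
            warnings.warn(
                f"standard {st.name!r} has sigma = {sigma:.3f} outside (0, 1); excluded",
                stacklevel=2,
            )
            continue
        usable.append((st, sigma))
    if len({round(s, 12) for _, s in usable}) < 3:
        raise ValueError("need at least 3 standards with distinct sigma in (0, 1)")

    z = np.array([erfcinv(sigma) for _, sigma in usable])
    rs = np.array([st.rs_A for st, _ in usable])
    design = np.column_stack([np.ones_like(z), z])
    coef, _, _, _ = np.linalg.lstsq(design, rs, rcond=None)
    a, b = float(coef[0]), float(coef[1])

    fitted = a + b * z
    resid = rs - fitted
    dof = len(usable) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        stderr_a, stderr_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        stderr_a = stderr_b = None
    return SECCalibration(
        a=a,
        b=b,
        stderr_a=stderr_a,
        stderr_b=stderr_b,
        residuals={st.name: float(r) for (st, _), r in zip(usable, resid)},
    )


def stokes_radius(sigma: float, cal: SECCalibration) -> float:
    """Rs = a + b*erfc^-1(sigma); strictly decreasing in sigma on (0, 1)."""
    if not 0.0 < sigma < 1.0:
        raise ValueError("sigma must lie strictly inside (0, 1)")
    return float(cal.a + cal.b * erfcinv(sigma))


def elution_volume(rs_A: float, cal: SECCalibration, column: SECColumn) -> float:
    """Inverse of the calibration: Ve that elutes a sphere of radius Rs."""
    sigma = float(erfc((rs_A - cal.a) / cal.b))
    return column.vo_ml + sigma * column.vi_ml


def sphere_radius(mass_kda: float, vbar: float = DEFAULT_VBAR) -> float:
    """Anhydrous sphere radius r0 (angstrom) for a protein of given mass.

    r0 = (3 M vbar / (4 pi N_Av))^(1/3); scales as M^(1/3) at fixed
    partial specific volume ``vbar`` (cm^3/g, default 0.73).
    """
    if mass_kda <= 0 or vbar <= 0:
        raise ValueError("mass and vbar must be positive")
    mass_g_mol = mass_kda * 1e3
    r_cm = (3.0 * mass_g_mol * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)
    return float(r_cm * 1e8)


def wilkins_radius(n_residues: float, prefactor: float = 4.75, exponent: float = 0.29) -> float:
    """Folded-chain Stokes radius Rs = 4.75 * N^0.29 (angstrom)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    return float(prefactor * n_residues**exponent)


def correlation_time(t2_ms: float) -> float:
    """Rotational correlation time tau_c ~ 1/(5 T2), in ns.

    The rule carries an inherent ~10% uncertainty
    (:data:`TAU_C_RELATIVE_UNCERTAINTY`).
    """
    if t2_ms <= 0:
        raise ValueError("T2 must be positive")
    return float(1.0 / (5.0 * t2_ms * 1e-3))


def mw_from_correlation_time(tau_c_ns: float, k_kda_per_ns: float = 2.0) -> float:
    """Linear molecular-mass estimate MW = k * tau_c (kDa), ~10% band."""
    if tau_c_ns <= 0:
        raise ValueError("correlation time must be positive")
    return float(k_kda_per_ns * tau_c_ns)
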