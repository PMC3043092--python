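"""Seeded synthetic-data generators for every input class the pipeline fits.

No raw instrument data are deposited for these proteins, so the fitting
stages are validated on forward-model data with known ground truth. All
generators share the contract: zero noise reproduces the forward model
to machine precision, the same seed reproduces the same output, and the
generating parameters are embedded in the curve metadata so they
round-trip through the CSV files.

Noise is homoscedastic Gaussian, parameterised either as a fraction of
the signal amplitude (so scenarios transfer across probes with very
different signal scales) or in absolute units.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .chem import (
    ThreeStateChemParams,
    TwoStateChemParams,
    three_state_chem_signal,
    two_state_chem_signal,
)
from .constants import WAVELENGTH_MAX, WAVELENGTH_MIN, WAVELENGTH_STEP
from .curves import DenaturationCurve, EmissionSpectrum
from .dsc import DSCParams, dsc_excess_cp
from .hydro import CalibrationStandard, SECCalibration, SECColumn, elution_volume
from .thermal import ThermalParams, thermal_signal
from .titration import (
    DoubleTransitionParams,
    SingleTransitionParams,
    bell_signal,
    single_pka_signal,
)

__all__ = [
    "NoiseSpec",
    "gen_chem_curve",
    "gen_thermal_curve",
    "gen_titration",
    "gen_dsc_endotherm",
    "gen_sec_standards",
    "gen_spectrum_series",
]

#: Default acquisition grids mirroring the experimental settings.
DEFAULT_CHEM_GRID = np.linspace(0.0, 7.0, 30)  # M GdmCl (7 M stock)
DEFAULT_THERMAL_GRID = np.arange(25.0, 95.0 + 1e-9, 0.2)  # degC, 0.2 degC pitch
DEFAULT_PH_GRID = np.arange(2.0, 13.0 + 1e-9, 0.5)  # buffer series


@dataclass
class NoiseSpec:
    """Gaussian noise description: sigma as amplitude fraction or absolute."""

    sigma: float
    seed: int = 0
    kind: str = "gaussian"
    absolute: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")


def _apply_noise(y: np.ndarray, noise: NoiseSpec | None) -> np.ndarray:
    if noise is None or noise.sigma == 0:
        return y
    rng = np.random.default_rng(noise.seed)
    scale = noise.sigma if noise.absolute else noise.sigma * float(np.ptp(y))
    return y + rng.normal(0.0, scale, size=y.shape)


def gen_chem_curve(
    params: TwoStateChemParams | ThreeStateChemParams,
    grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    probe: str = "fluorescence",
) -> DenaturationCurve:
    """Forward-model a GdmCl denaturation curve (two- or three-state)."""
    grid = DEFAULT_CHEM_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 7.0:
        raise ValueError("denaturant grid must stay within the 0-7 M stock range")
    if isinstance(params, TwoStateChemParams):
        y = two_state_chem_signal(params, grid)
        model = "two_state_chem"
    else:
        y = three_state_chem_signal(params, grid)
        model = "three_state_chem"
    return DenaturationCurve(
        axis_kind="denaturant",
        x=grid,
        y=_apply_noise(np.asarray(y, dtype=float), noise),
        probe=probe,
        meta={"truth": {"model": model, **asdict(params)},
              "noise": asdict(noise) if noise else None},
    )


def gen_thermal_curve(
    params: ThermalParams,
    grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    probe: str = "cd",
) -> DenaturationCurve:
    """Forward-model a thermal melting curve on the 25-95 degC scan grid."""
    grid = DEFAULT_THERMAL_GRID if grid is None else np.asarray(grid, dtype=float)
    y = np.asarray(thermal_signal(params, grid), dtype=float)
    return DenaturationCurve(
        axis_kind="temperature",
        x=grid,
        y=_apply_noise(y, noise),
        probe=probe,
        meta={"truth": {"model": "thermal_two_state", **asdict(params)},
              "noise": asdict(noise) if noise else None},
    )


def gen_titration(
    params: SingleTransitionParams | DoubleTransitionParams,
    grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    probe: str = "fluorescence",
) -> DenaturationCurve:
    """Forward-model a pH titration (single sigmoid or bell)."""
    grid = DEFAULT_PH_GRID if grid is None else np.asarray(grid, dtype=float)
    if isinstance(params, SingleTransitionParams):
        y = single_pka_signal(params, grid)
        model = "single_pka"
    else:
        y = bell_signal(params, grid)
        model = "double_pka"
    return DenaturationCurve(
        axis_kind="pH",
        x=grid,
        y=_apply_noise(np.asarray(y, dtype=float), noise),
        probe=probe,
        meta={"truth": {"model": model, **asdict(params)},
              "noise": asdict(noise) if noise else None},
    )


def gen_dsc_endotherm(
    params: DSCParams,
    grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> DenaturationCurve:
    """Forward-model a baseline-subtracted DSC endotherm (0.05 degC grid)."""
    if grid is None:
        lo = min(t.tm_C for t in params.transitions) - 30.0
        hi = max(t.tm_C for t in params.transitions) + 30.0
        grid = np.arange(lo, hi + 1e-9, 0.05)
    else:
        grid = np.asarray(grid, dtype=float)
    y = np.asarray(dsc_excess_cp(params, grid), dtype=float)
    return DenaturationCurve(
        axis_kind="temperature",
        x=grid,
        y=_apply_noise(y, noise),
        probe="dsc",
        meta={
            "truth": {
                "model": f"dsc_{params.model_kind}",
                "transitions": [asdict(t) for t in params.transitions],
                "scale": params.scale,
            },
            "noise": asdict(noise) if noise else None,
        },
    )


def gen_sec_standards(
    cal: SECCalibration,
    column: SECColumn,
    rs_list: list[float] | None = None,
    sigma_ve_ml: float = 0.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> list[CalibrationStandard]:
    """Standards with elution volumes implied by a known calibration line.

    Defaults to the four-protein low-molecular-weight kit radii
    (16.4, 20.9, 30.5, 35.5 angstrom). Gaussian noise of ``sigma_ve_ml``
    ml is added to the elution volumes when requested.
    """
    from .tables import STANDARD_RADII

    if rs_list is None:
        rs_list = list(STANDARD_RADII.values())
        names = names or list(STANDARD_RADII)
    names = names or [f"standard_{i}" for i in range(len(rs_list))]
    rng = np.random.default_rng(seed)
    out = []
    for name, rs in zip(names, rs_list):
        ve = elution_volume(rs, cal, column)
        if sigma_ve_ml > 0:
            ve += rng.normal(0.0, sigma_ve_ml)
        out.append(CalibrationStandard(name, rs, float(ve)))
    return out


def gen_spectrum_series(
    unfolded_fractions,
    folded_max_nm: float = 335.0,
    unfolded_max_nm: float = 351.0,
    bandwidth_nm: float = 10.0,
    axis_kind: str = "denaturant",
    conditions=None,
    grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    excitation_nm: float = 280.0,
    folded_amplitude: float = 1.0,
    unfolded_amplitude: float = 1.0,
) -> list[EmissionSpectrum]:
    """Emission spectra for a schedule of unfolded fractions.

    Each spectrum is a two-component Gaussian-band mixture: a folded
    band centred at ``folded_max_nm`` with weight (1 - f) and an
    unfolded band at ``unfolded_max_nm`` with weight f, both of standard
    deviation ``bandwidth_nm`` on the 300-400 nm / 1 nm acquisition
    grid. With equal band amplitudes the intensity-weighted mean
    wavelength interpolates (to within grid-truncation error) between
    the two band centres.
    """
    fractions = np.asarray(unfolded_fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("unfolded fractions must lie in [0, 1]")
    if grid is None:
        grid = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1e-9, WAVELENGTH_STEP)
    if conditions is None:
        conditions = np.arange(fractions.size, dtype=float)
    conditions = np.asarray(conditions, dtype=float)
    if conditions.size != fractions.size:
        raise ValueError("conditions and fractions differ in length")

    rng = np.random.default_rng(noise.seed) if noise else None
    spectra = []
    for f, cond in zip(fractions, conditions):
        folded = folded_amplitude * np.exp(
            -0.5 * ((grid - folded_max_nm) / bandwidth_nm) ** 2
        )
        unfolded = unfolded_amplitude * np.exp(
            -0.5 * ((grid - unfolded_max_nm) / bandwidth_nm) ** 2
        )
        intensity = (1.0 - f) * folded + f * unfolded
        if noise is not None and noise.sigma > 0:
            scale = noise.sigma if noise.absolute else noise.sigma * float(intensity.max())
            intensity = np.clip(intensity + rng.normal(0.0, scale, grid.shape), 0.0, None)
        spectra.append(
            EmissionSpectrum(
                wavelengths=grid.copy(),
                intensities=intensity,
                axis_kind=axis_kind,
                condition=float(cond),
                excitation_nm=excitation_nm,
            )
        )
    return spectra
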