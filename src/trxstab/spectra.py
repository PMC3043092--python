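"""Scalar observables extracted from emission spectra.

The workhorse is the intensity-weighted average emission wavelength
``<lambda> = sum(lambda_i * I_i) / sum(I_i)``, a robust reporter of
tryptophan solvent exposure that is far more sensitive to spectral
shifts than the intensity at any single wavelength.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np

from .curves import DenaturationCurve, EmissionSpectrum


def average_emission_wavelength(spectrum: EmissionSpectrum) -> float:
    """Intensity-weighted mean emission wavelength ``<lambda>`` in nm.

    Invariant under rescaling all intensities by a positive constant and
    always bounded by the wavelength grid extremes.

    Raises
    ------
    ValueError
        If the total intensity is zero (degenerate spectrum).
    """
    total = spectrum.intensities.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all intensities are zero")
    return float((spectrum.wavelengths * spectrum.intensities).sum() / total)


def intensity_at(spectrum: EmissionSpectrum, wavelength_nm: float) -> float:
    """Intensity at the grid point nearest ``wavelength_nm``.

    Warns when the nearest grid point is more than 0.5 nm away from the
    requested wavelength.
    """
    idx = int(np.argmin(np.abs(spectrum.wavelengths - wavelength_nm)))
    gap = abs(float(spectrum.wavelengths[idx]) - wavelength_nm)
    if gap > 0.5:
        warnings.warn(
            f"requested {wavelength_nm} nm is {gap:.2f} nm off the grid; "
            f"using nearest point {spectrum.wavelengths[idx]} nm",
            stacklevel=2,
        )
    return float(spectrum.intensities[idx])


def spectra_to_curve(
    spectra: Sequence[EmissionSpectrum],
    observable: str = "avg_wavelength",
    wavelength_nm: float | None = None,
    probe: str = "fluorescence",
) -> DenaturationCurve:
    """Collapse a series of spectra into a single denaturation curve.

    Parameters
    ----------
    spectra : sequence of EmissionSpectrum
        All spectra must share the same axis kind and excitation
        wavelength; one point per spectrum.
    observable : {"avg_wavelength", "intensity_at"}
        Scalar observable used as the curve signal.
    wavelength_nm : float, optional
        Required for ``observable="intensity_at"``.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to build a curve")
    kinds = {s.axis_kind for s in spectra}
    if len(kinds) > 1:
        raise ValueError(f"mixed axis kinds {sorted(kinds)}")
    excitations = {s.excitation_nm for s in spectra}
    if len(excitations) > 1:
        raise ValueError(f"mixed excitation wavelengths {sorted(excitations, key=str)}")

    if observable == "avg_wavelength":
        y = [average_emission_wavelength(s) for s in spectra]
    elif observable == "intensity_at":
        if wavelength_nm is None:
            raise ValueError("intensity_at requires wavelength_nm")
        y = [intensity_at(s, wavelength_nm) for s in spectra]
    else:
        raise ValueError(f"unknown observable {observable!r}")

    return DenaturationCurve(
        axis_kind=spectra[0].axis_kind,
        x=np.array([s.condition for s in spectra], dtype=float),
        y=np.asarray(y, dtype=float),
        probe=probe,
        meta={"observable": observable},
    )


def normalize_to_lowest_condition(curve: DenaturationCurve) -> DenaturationCurve:
    """Divide the signal by its value at the lowest condition.

    This is the convention used to overlay curves from different probes
    on a common scale: the first point becomes exactly 1 and the
    operation is idempotent. Sign is preserved, so negative signals
    (e.g. far-UV ellipticity) normalise to 1 at the lowest condition as
    well.
    """
    ref = curve.y[0]
    if ref == 0:
        raise ValueError("signal at the lowest condition is zero")
    return DenaturationCurve(
        axis_kind=curve.axis_kind,
        x=curve.x.copy(),
        y=curve.y / ref,
        probe=curve.probe,
        meta={**curve.meta, "normalized": True},
    )
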