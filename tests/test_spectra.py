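"""Spectral observables: weighted mean wavelength, curve assembly, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trxstab import (
    DenaturationCurve,
    EmissionSpectrum,
    average_emission_wavelength,
    gen_spectrum_series,
    normalize_to_lowest_condition,
    spectra_to_curve,
)

GRID = np.arange(300.0, 401.0)


def _spectrum(intensities, condition=7.0, axis_kind="pH"):
    return EmissionSpectrum(GRID, intensities, axis_kind, condition, excitation_nm=280.0)


class TestAverageEmissionWavelength:
    def test_point_mass_returns_its_wavelength(self):
        intens = np.zeros(GRID.size)
        intens[GRID == 340.0] = 5.0
        assert average_emission_wavelength(_spectrum(intens)) == pytest.approx(340.0)

    def test_uniform_spectrum_gives_grid_midpoint(self):
        assert average_emission_wavelength(_spectrum(np.ones(GRID.size))) == pytest.approx(350.0)

    def test_two_point_weighted_mean(self):
        # hand-computed: (320*1 + 360*3) / 4 = 350
        spec = EmissionSpectrum([320.0, 360.0], [1.0, 3.0], "pH", 7.0)
        assert average_emission_wavelength(spec) == pytest.approx(350.0)

    def test_all_zero_intensities_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            average_emission_wavelength(_spectrum(np.zeros(GRID.size)))

    @settings(max_examples=50, derandomize=True)
    @given(
        intens=arrays(float, GRID.size, elements=st.floats(0.0, 1e6)),
        scale=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance_and_bounds(self, intens, scale):
        if intens.sum() <= 0:
            return
        lam = average_emission_wavelength(_spectrum(intens))
        lam_scaled = average_emission_wavelength(_spectrum(intens * scale))
        assert 300.0 <= lam <= 400.0
        assert lam_scaled == pytest.approx(lam, rel=1e-9)


class TestSpectraToCurve:
    def test_constant_spectra_give_flat_curve(self):
        spectra = [_spectrum(np.ones(GRID.size), condition=ph) for ph in (3.0, 7.0, 11.0)]
        curve = spectra_to_curve(spectra)
        assert np.allclose(curve.y, 350.0)

    def test_moving_point_mass_gives_monotone_curve(self):
        spectra = []
        for i, (wl, gdm) in enumerate(zip((330.0, 340.0, 350.0), (0.0, 2.0, 4.0))):
            intens = np.zeros(GRID.size)
            intens[GRID == wl] = 1.0
            spectra.append(EmissionSpectrum(GRID, intens, "denaturant", gdm, 280.0))
        curve = spectra_to_curve(spectra)
        assert np.all(np.diff(curve.y) > 0)

    def test_forward_model_round_trip(self):
        fractions = np.linspace(0.0, 1.0, 11)
        spectra = gen_spectrum_series(fractions, conditions=np.linspace(0, 5, 11))
        curve = spectra_to_curve(spectra)
        expected = [average_emission_wavelength(s) for s in spectra]
        assert np.allclose(curve.y, expected, atol=1e-9)

    def test_mixed_axis_kinds_rejected(self):
        a = _spectrum(np.ones(GRID.size), condition=3.0, axis_kind="pH")
        b = EmissionSpectrum(GRID, np.ones(GRID.size), "denaturant", 1.0, 280.0)
        with pytest.raises(ValueError, match="mixed axis"):
            spectra_to_curve([a, b])

    def test_off_grid_wavelength_warns_on_coarse_grid(self):
        coarse = np.array([320.0, 340.0, 360.0])
        spectra = [
            EmissionSpectrum(coarse, np.ones(3), "pH", ph, 280.0) for ph in (3.0, 7.0)
        ]
        with pytest.warns(UserWarning, match="off the grid"):
            spectra_to_curve(spectra, observable="intensity_at", wavelength_nm=345.0)

    def test_on_grid_wavelength_selected_exactly(self):
        spectra = [_spectrum(np.ones(GRID.size), condition=ph) for ph in (3.0, 7.0)]
        curve = spectra_to_curve(spectra, observable="intensity_at", wavelength_nm=340.0)
        assert np.allclose(curve.y, 1.0)


class TestNormalization:
    def test_direct_division(self):
        curve = DenaturationCurve("pH", [2.0, 7.0, 12.0], [2.0, 4.0, 6.0])
        assert np.allclose(normalize_to_lowest_condition(curve).y, [1.0, 2.0, 3.0])

    def test_sign_preserving_for_ellipticity(self):
        curve = DenaturationCurve("pH", [2.0, 7.0], [-10.0, -5.0], probe="cd")
        assert np.allclose(normalize_to_lowest_condition(curve).y, [1.0, 0.5])

    def test_idempotent(self):
        curve = DenaturationCurve("pH", [2.0, 7.0, 12.0], [3.0, 6.0, 1.5])
        once = normalize_to_lowest_condition(curve)
        twice = normalize_to_lowest_condition(once)
        assert np.allclose(once.y, twice.y)
        assert once.y[0] == 1.0

    def test_zero_reference_raises(self):
        curve = DenaturationCurve("pH", [2.0, 7.0], [0.0, 5.0])
        with pytest.raises(ValueError, match="zero"):
            normalize_to_lowest_condition(curve)


class TestContainers:
    def test_conflicting_duplicate_x_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            DenaturationCurve("pH", [2.0, 2.0, 7.0], [1.0, 1.5, 3.0])

    def test_exact_duplicates_collapsed_and_sorted(self):
        curve = DenaturationCurve("pH", [7.0, 2.0, 2.0], [3.0, 1.0, 1.0])
        assert np.allclose(curve.x, [2.0, 7.0])
        assert np.allclose(curve.y, [1.0, 3.0])

    def test_curve_csv_round_trip(self, tmp_path):
        curve = DenaturationCurve(
            "denaturant", [0.0, 1.0, 2.0], [1.0, 0.5, 0.1],
            probe="cd", meta={"truth": {"m": 2.3, "u50": 3.19}},
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = DenaturationCurve.from_csv(path)
        assert back.axis_kind == "denaturant" and back.probe == "cd"
        assert np.array_equal(back.x, curve.x) and np.array_equal(back.y, curve.y)
        assert back.meta["truth"] == {"m": 2.3, "u50": 3.19}

    def test_spectrum_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            EmissionSpectrum([300.0, 300.0], [1.0, 1.0], "pH", 7.0)
        with pytest.raises(ValueError, match="negative"):
            EmissionSpectrum([300.0, 301.0], [1.0, -1.0], "pH", 7.0)
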