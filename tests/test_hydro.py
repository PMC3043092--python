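"""SEC calibration, partition coefficients and theoretical size estimators."""

import numpy as np
import pytest
from scipy.special import erfc, erfcinv

from trxstab import (
    CalibrationStandard,
    SECCalibration,
    SECColumn,
    correlation_time,
    elution_volume,
    fit_sec_calibration,
    gen_sec_standards,
    mw_from_correlation_time,
    partition_coefficient,
    sphere_radius,
    stokes_radius,
    wilkins_radius,
)

COLUMN = SECColumn(vo_ml=7.88, vi_ml=18.72)
CAL = SECCalibration(a=1.69, b=26.7)


class TestPartitionCoefficient:
    def test_void_limit(self):
        assert partition_coefficient(7.88, COLUMN) == 0.0

    def test_total_volume_limit(self):
        assert partition_coefficient(7.88 + 18.72, COLUMN) == pytest.approx(1.0)

    def test_monomer_elution_volume(self):
        assert partition_coefficient(13.3, COLUMN) == pytest.approx(0.2895, abs=1e-4)

    def test_pre_void_elution_rejected(self):
        with pytest.raises(ValueError, match="void"):
            partition_coefficient(5.0, COLUMN)

    def test_interaction_regime_warns(self):
        with pytest.warns(UserWarning, match="interaction"):
            partition_coefficient(27.5, COLUMN)


class TestCalibration:
    def test_exact_recovery_from_noiseless_standards(self):
        standards = gen_sec_standards(CAL, COLUMN)
        fit = fit_sec_calibration(standards, COLUMN)
        assert fit.a == pytest.approx(1.69, abs=1e-9)
        assert fit.b == pytest.approx(26.7, abs=1e-9)

    def test_two_standards_underdetermined(self):
        standards = gen_sec_standards(CAL, COLUMN, rs_list=[16.4, 35.5])
        with pytest.raises(ValueError, match="at least 3"):
            fit_sec_calibration(standards, COLUMN)

    def test_out_of_range_standard_excluded_with_warning(self):
        standards = gen_sec_standards(CAL, COLUMN)
        standards.append(CalibrationStandard("stuck", 10.0, 30.0))
        with pytest.warns(UserWarning, match="excluded"):
            fit = fit_sec_calibration(standards, COLUMN)
        assert fit.a == pytest.approx(1.69, abs=1e-9)

    def test_noisy_standards_unbiased(self):
        a_vals, b_vals = [], []
        for seed in range(200):
            standards = gen_sec_standards(CAL, COLUMN, sigma_ve_ml=0.1, seed=seed)
            fit = fit_sec_calibration(standards, COLUMN)
            a_vals.append(fit.a)
            b_vals.append(fit.b)
        for vals, truth in ((a_vals, 1.69), (b_vals, 26.7)):
            arr = np.asarray(vals)
            se = arr.std(ddof=1) / np.sqrt(arr.size)
            assert abs(arr.mean() - truth) < 3 * se

    def test_stokes_radius_from_monomer_elution(self):
        sigma = partition_coefficient(13.3, COLUMN)
        # the printed calibration line maps sigma=0.2895 to ~21.7 A
        assert stokes_radius(sigma, CAL) == pytest.approx(21.7, abs=0.05)

    def test_round_trip_ve_sigma_rs(self):
        for ve in (10.0, 13.3, 18.0, 24.0):
            sigma = partition_coefficient(ve, COLUMN)
            rs = stokes_radius(sigma, CAL)
            assert elution_volume(rs, CAL, COLUMN) == pytest.approx(ve, abs=1e-9)

    def test_monotone_decreasing_in_sigma(self):
        assert stokes_radius(0.2, CAL) > stokes_radius(0.4, CAL)

    def test_sigma_at_total_volume_undefined(self):
        with pytest.raises(ValueError):
            stokes_radius(1.0, CAL)

    def test_erfcinv_identities(self):
        assert erfcinv(1.0) == 0.0
        x = np.linspace(1e-6, 1 - 1e-6, 101)
        assert np.allclose(erfc(erfcinv(x)), x, atol=1e-12)


class TestTheoreticalEstimators:
    @pytest.mark.parametrize(
        "mass,expected", [(13.1, 15.6), (13.0, 15.5), (12.1, 15.2)]
    )
    def test_sphere_radius_reproduces_reference(self, mass, expected):
        assert sphere_radius(mass) == pytest.approx(expected, abs=0.1)

    def test_sphere_radius_cube_root_scaling(self):
        assert sphere_radius(26.2) == pytest.approx(sphere_radius(13.1) * 2 ** (1 / 3))

    @pytest.mark.parametrize("n,printed", [(120, 19), (118, 19), (109, 18)])
    def test_wilkins_radius_matches_reference_at_print_precision(self, n, printed):
        # reference values are printed to the nearest angstrom
        assert abs(wilkins_radius(n) - printed) < 1.0

    def test_wilkins_radius_direct_evaluations(self):
        assert round(wilkins_radius(120), 1) == pytest.approx(19.0)
        assert round(wilkins_radius(109), 1) == pytest.approx(18.5)

    def test_wilkins_single_residue(self):
        assert wilkins_radius(1) == pytest.approx(4.75)

    def test_correlation_time_values(self):
        assert correlation_time(30.0) == pytest.approx(6.667, abs=1e-3)
        assert correlation_time(30.5) == pytest.approx(6.56, abs=5e-3)
        assert correlation_time(60.0) == pytest.approx(correlation_time(30.0) / 2)

    def test_mass_estimate(self):
        assert mw_from_correlation_time(6.7) == pytest.approx(13.4)
        assert mw_from_correlation_time(6.7, k_kda_per_ns=1.0) == pytest.approx(6.7)
        # tau_c = 6.9 ns maps to 13.8 kDa, within 10% of the reported 13.7
        assert abs(mw_from_correlation_time(6.9) - 13.7) / 13.7 < 0.10
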