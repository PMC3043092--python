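"""Chemical denaturation: LEM free energy, two-/three-state signals and fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trxstab import (
    NoiseSpec,
    ThreeStateChemParams,
    TwoStateChemParams,
    fit_three_state_chem,
    fit_two_state_chem,
    gen_chem_curve,
    lem_free_energy,
    three_state_chem_signal,
    three_state_populations,
    two_state_chem_signal,
)
from trxstab.constants import R_KCAL

RT25 = R_KCAL * 298.15


class TestLemFreeEnergy:
    def test_water_extrapolation_reproduces_reported_dg(self):
        # m = 2.3 kcal/mol/M, U50 = 3.19 M -> dG(0) = 7.337 ~ 7.3 kcal/mol
        assert lem_free_energy(2.3, 3.19, 0.0) == pytest.approx(7.337)

    def test_zero_at_midpoint(self):
        assert lem_free_energy(2.3, 3.19, 3.19) == 0.0

    def test_hand_arithmetic(self):
        assert lem_free_energy(1.9, 2.00, 1.0) == pytest.approx(1.9)

    def test_nonpositive_m_rejected(self):
        with pytest.raises(ValueError):
            lem_free_energy(-1.0, 3.0, 0.0)


class TestTwoStateSignal:
    def test_midpoint_with_flat_baselines(self):
        p = TwoStateChemParams(1.0, 0.0, 0.0, 0.0, 2.3, 3.19)
        assert two_state_chem_signal(p, 3.19) == pytest.approx(0.5)

    def test_native_limit(self):
        p = TwoStateChemParams(1.0, -0.02, 0.0, 0.0, 2.3, 3.19)
        assert two_state_chem_signal(p, 0.0) == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_at_4M(self):
        # independent closed-form evaluation of the Boltzmann mixture
        p = TwoStateChemParams(1.0, 0.0, 0.0, 0.0, 2.3, 3.19)
        k = np.exp(2.3 * (4.0 - 3.19) / RT25)
        assert two_state_chem_signal(p, 4.0) == pytest.approx(1.0 / (1.0 + k), rel=1e-12)
        frac = k / (1.0 + k)
        assert frac == pytest.approx(0.958, abs=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(u=st.floats(0.0, 7.0), m=st.floats(0.5, 5.0), u50=st.floats(0.5, 6.0))
    def test_signal_bounded_by_baselines(self, u, m, u50):
        p = TwoStateChemParams(1.0, -0.01, 0.1, 0.02, m, u50)
        sig = two_state_chem_signal(p, u)
        lo = min(1.0 - 0.01 * u, 0.1 + 0.02 * u)
        hi = max(1.0 - 0.01 * u, 0.1 + 0.02 * u)
        assert lo - 1e-9 <= sig <= hi + 1e-9


class TestThreeStateSignal:
    def test_degenerate_limit_matches_closed_form(self):
        # alpha_I at the baseline midpoint with coincident transitions:
        # X = (1 + 0.5 K)/(1 + K + K^2); independent closed-form evaluation
        three = ThreeStateChemParams(1.0, 0.0, 0.5, 0.0, 0.0, 2.0, 3.0, 2.0, 3.0)
        u = np.linspace(0, 7, 50)
        k = np.exp(-2.0 * (3.0 - u) / RT25)
        expected = (1.0 + 0.5 * k) / (1.0 + k + k * k)
        assert np.allclose(three_state_chem_signal(three, u), expected, atol=1e-12)
        # the f_N = f_U midpoint still sits at U50
        f_n, _, f_u = three_state_populations(three, 3.0)
        assert f_n == pytest.approx(f_u)

    @settings(max_examples=50, derandomize=True)
    @given(u=st.floats(0.0, 7.0))
    def test_populations_sum_to_one(self, u):
        p = ThreeStateChemParams(1.0, 0.0, 0.5, 0.0, 0.0, 1.4, 1.56, 2.6, 2.62)
        f_n, f_i, f_u = three_state_populations(p, u)
        assert f_n + f_i + f_u == pytest.approx(1.0, abs=1e-12)

    def test_ordering_convention_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            ThreeStateChemParams(1, 0, 0.5, 0, 0, 2.0, 3.0, 2.0, 1.0)


class TestTwoStateFit:
    TRUTH = TwoStateChemParams(1.0, -0.01, 0.1, 0.005, 2.3, 3.19)

    def test_noiseless_recovery(self):
        curve = gen_chem_curve(self.TRUTH)
        result = fit_two_state_chem(curve)
        assert result.converged
        assert result["m"] == pytest.approx(2.3, rel=1e-6)
        assert result["u50"] == pytest.approx(3.19, rel=1e-6)
        assert result.meta["dG_water_kcal_mol"] == pytest.approx(7.337, rel=1e-5)

    def test_fixed_parameter_pins(self):
        curve = gen_chem_curve(self.TRUTH)
        result = fit_two_state_chem(curve, fixed={"m": 2.3})
        assert result.params["m"] == 2.3
        assert result.stderr["m"] is None
        assert result.fixed == {"m": 2.3}

    def test_truncated_curve_flags_denatured_baseline(self):
        curve = gen_chem_curve(self.TRUTH, grid=np.linspace(0.0, 3.3, 12))
        result = fit_two_state_chem(curve)
        assert "unreliable_denatured_baseline" in result.flags

    def test_wrong_axis_rejected(self):
        curve = gen_chem_curve(self.TRUTH)
        bad = type(curve)("pH", curve.x, curve.y)
        with pytest.raises(ValueError, match="denaturant"):
            fit_two_state_chem(bad)

    def test_noisy_recovery_close_to_truth(self):
        curve = gen_chem_curve(self.TRUTH, noise=NoiseSpec(sigma=0.02, seed=7))
        result = fit_two_state_chem(curve, seed=7)
        assert result["u50"] == pytest.approx(3.19, rel=0.02)


class TestThreeStateFit:
    THERMO = dict(m1=1.4, u50_1=1.56, m2=2.6, u50_2=2.62)
    GRID = np.linspace(0.0, 5.5, 35)

    def _probe_pair(self):
        cd = ThreeStateChemParams(1.0, -0.01, 0.2, 0.05, 0.002, **self.THERMO)
        fl = ThreeStateChemParams(1.0, 0.005, 0.93, 0.1, -0.003, **self.THERMO)
        return (
            gen_chem_curve(cd, self.GRID, probe="cd"),
            gen_chem_curve(fl, self.GRID, probe="fluorescence"),
        )

    def test_joint_fit_recovers_shared_thermodynamics(self):
        result = fit_three_state_chem(self._probe_pair())
        for name, truth in self.THERMO.items():
            assert result[name] == pytest.approx(truth, rel=1e-4), name
        assert result["u50_1"] <= result["u50_2"]
        assert not result.flags

    def test_single_curve_recovery(self):
        cd = ThreeStateChemParams(1.0, -0.01, 0.2, 0.05, 0.002, **self.THERMO)
        result = fit_three_state_chem(gen_chem_curve(cd, self.GRID, probe="cd"))
        assert result["u50_1"] == pytest.approx(1.56, rel=1e-4)
        assert result["u50_2"] == pytest.approx(2.62, rel=1e-4)

    def test_two_state_data_raises_intermediate_flag(self):
        curve = gen_chem_curve(
            TwoStateChemParams(1.0, -0.01, 0.1, 0.005, 2.3, 3.19), self.GRID
        )
        result = fit_three_state_chem(curve)
        assert "two_state_recommended" in result.flags
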