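"""Thermal unfolding: Gibbs-Helmholtz free energy and melting-curve fits.

The unfolding free energy at absolute temperature T is

    dG(T) = dH(Tm) * (1 - T/Tm) + dCp * [(T - Tm) - T*ln(T/Tm)],

which vanishes at the midpoint Tm by construction and reduces to the
van't Hoff form when dCp = 0. Because the two-state signal expression
depends on dG only through exp(-dG/RT), the fitted Tm is insensitive to
whether dCp is pinned to the standard 1.2 kcal mol^-1 K^-1 or left
free; both modes are supported.

Temperatures cross the interface in degrees Celsius and are converted
to Kelvin internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .constants import CELSIUS_OFFSET, DEFAULT_DCP, R_KCAL
from .curves import DenaturationCurve
from .fitting import FitResult, run_fit, sigmoid_init

__all__ = ["ThermalParams", "gibbs_helmholtz", "thermal_signal", "fit_thermal"]


@dataclass
class ThermalParams:
    """Two-state thermal model: midpoint, enthalpy, dCp and linear baselines.

    Baselines are linear in Celsius temperature. ``dS(Tm) = dH/Tm`` is
    available as a property (kcal mol^-1 K^-1).
    """

    tm_C: float
    dH: float  # kcal/mol at Tm
    dCp: float = DEFAULT_DCP  # kcal mol^-1 K^-1
    alpha_N: float = 1.0
    beta_N: float = 0.0
    alpha_D: float = 0.0
    beta_D: float = 0.0

    def __post_init__(self) -> None:
        if self.tm_C + CELSIUS_OFFSET <= 0:
            raise ValueError("Tm must be above 0 K")
        if self.dH <= 0:
            raise ValueError("unfolding endotherm requires dH > 0")

    @property
    def tm_K(self) -> float:
        return self.tm_C + CELSIUS_OFFSET

    @property
    def dS(self) -> float:
        return self.dH / self.tm_K


def gibbs_helmholtz(dH: float, tm_K: float, dCp: float, t_K) -> float | np.ndarray:
    """dG(T) in kcal/mol from midpoint enthalpy, Tm and dCp (all-Kelvin)."""
    t_K = np.asarray(t_K, dtype=float)
    if tm_K <= 0 or np.any(t_K <= 0):
        raise ValueError("absolute temperatures must be positive")
    dg = dH * (1.0 - t_K / tm_K) + dCp * ((t_K - tm_K) - t_K * np.log(t_K / tm_K))
    return float(dg) if dg.ndim == 0 else dg


def thermal_signal(p: ThermalParams, t_C):
    """Two-state melting-curve signal at Celsius temperature(s) ``t_C``."""
    t_C = np.asarray(t_C, dtype=float)
    t_K = t_C + CELSIUS_OFFSET
    dg = gibbs_helmholtz(p.dH, p.tm_K, p.dCp, t_K)
    k = np.exp(-dg / (R_KCAL * t_K))
    x_n = p.alpha_N + p.beta_N * t_C
    x_d = p.alpha_D + p.beta_D * t_C
    out = (x_n + x_d * k) / (1.0 + k)
    return float(out) if out.ndim == 0 else out


def fit_thermal(
    curve: DenaturationCurve,
    dcp_mode: str = "fixed",
    dcp_value: float = DEFAULT_DCP,
    init: dict | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the two-state thermal model to a temperature-axis curve.

    Parameters
    ----------
    curve : DenaturationCurve
        ``axis_kind`` must be ``temperature``; x in degC.
    dcp_mode : {"fixed", "free"}
        Whether dCp is pinned at ``dcp_value`` or estimated.

    Returns
    -------
    FitResult
        ``tm_C`` (degC), ``dH`` (kcal/mol), ``dCp`` and baselines; the
        derived entropy ``dS(Tm)`` sits in ``meta``. Flags:
        ``extrapolated_midpoint`` when Tm falls outside the scanned
        range, ``unreliable_unfolded_baseline`` when fewer than two
        points lie past the transition.
    """
    if curve.axis_kind != "temperature":
        raise ValueError("fit_thermal expects a temperature-axis curve")
    if len(curve) < 8:
        raise ValueError("need at least 8 points")
    if dcp_mode not in ("fixed", "free"):
        raise ValueError("dcp_mode must be 'fixed' or 'free'")

    guess = sigmoid_init(curve.x, curve.y)
    tm0 = guess["midpoint"]
    # slope of the unfolded fraction at Tm ~ dH/(4*R*Tm^2)
    tm0_K = tm0 + CELSIUS_OFFSET
    dh0 = float(np.clip(4.0 * R_KCAL * tm0_K**2 * abs(guess["central_slope"]), 20.0, 250.0))
    defaults = {
        "alpha_N": guess["alpha_N"],
        "beta_N": guess["beta_N"],
        "alpha_D": guess["alpha_D"],
        "beta_D": guess["beta_D"],
        "tm_C": tm0,
        "dH": dh0,
        "dCp": dcp_value,
    }
    if init:
        defaults.update(init)

    params = lmfit.Parameters()
    for name in ("alpha_N", "beta_N", "alpha_D", "beta_D"):
        params.add(name, value=defaults[name])
    params.add("tm_C", value=defaults["tm_C"], min=-CELSIUS_OFFSET + 1.0)
    params.add("dH", value=defaults["dH"], min=1.0)
    params.add("dCp", value=defaults["dCp"], vary=(dcp_mode == "free"), min=0.0)

    def residual(p):
        model = ThermalParams(
            p["tm_C"].value, max(p["dH"].value, 1e-6), p["dCp"].value,
            p["alpha_N"].value, p["beta_N"].value,
            p["alpha_D"].value, p["beta_D"].value,
        )
        return curve.y - thermal_signal(model, curve.x)

    fixed = {"dCp": dcp_value} if dcp_mode == "fixed" else {}
    result = run_fit(residual, params, model="thermal_two_state", seed=seed, fixed=fixed)

    est = result.params
    tm_K = est["tm_C"] + CELSIUS_OFFSET
    if not (curve.x.min() <= est["tm_C"] <= curve.x.max()):
        result.flags.append("extrapolated_midpoint")
    t_K = curve.x + CELSIUS_OFFSET
    dg = gibbs_helmholtz(max(est["dH"], 1e-6), tm_K, est["dCp"], t_K)
    frac = 1.0 / (1.0 + np.exp(dg / (R_KCAL * t_K)))
    if int(np.sum(frac > 0.9)) < 2:
        result.flags.append("unreliable_unfolded_baseline")
    if not result.converged:
        result.flags.append("non_convergence")
    result.meta.update(
        {
            "dcp_mode": dcp_mode,
            "dS_kcal_mol_K": est["dH"] / tm_K,
            "tm_K": tm_K,
            "reversibility": "equilibrium model; reversibility not verified",
        }
    )
    return result
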