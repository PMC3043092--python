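"""Chemical (denaturant-induced) unfolding models and fits.

Two-state model
---------------
Under the linear extrapolation model (LEM) the unfolding free energy is
linear in denaturant concentration,

    dG(U) = m * (U50 - U)        [kcal/mol],

where ``m`` is the cooperativity slope (kcal mol^-1 M^-1) and ``U50``
the midpoint concentration. The observed signal mixes the native and
denatured baselines, each linear in denaturant,

    X(U) = [X_N + X_D * exp(-dG/RT)] / [1 + exp(-dG/RT)],
    X_N = alpha_N + beta_N*U,  X_D = alpha_D + beta_D*U.

Three-state extension
---------------------
A sequential N <-> I <-> U scheme with a constant intermediate signal
level ``alpha_I``:

    X(U) = [X_N + alpha_I*K1 + X_D*K1*K2] / [1 + K1 + K1*K2],
    K_i = exp(-m_i*(U50_i - U)/RT),

with the ordering convention U50_1 <= U50_2. Probe-dependent apparent
midpoints (e.g. far-UV CD reporting the first transition and
fluorescence the second) are handled by a joint fit sharing the
thermodynamic parameters across probes while each probe keeps its own
signal levels.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL
from .curves import DenaturationCurve
from .fitting import FitResult, run_fit, sigmoid_init

__all__ = [
    "TwoStateChemParams",
    "ThreeStateChemParams",
    "lem_free_energy",
    "unfolded_fraction",
    "two_state_chem_signal",
    "three_state_chem_signal",
    "three_state_populations",
    "fit_two_state_chem",
    "fit_three_state_chem",
]


@dataclass
class TwoStateChemParams:
    """Parameters of the two-state LEM signal model."""

    alpha_N: float
    beta_N: float
    alpha_D: float
    beta_D: float
    m: float  # kcal mol^-1 M^-1
    u50: float  # M
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.u50 < 0:
            raise ValueError("U50 must be non-negative")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ThreeStateChemParams:
    """Parameters of the sequential three-state LEM signal model."""

    alpha_N: float
    beta_N: float
    alpha_I: float
    alpha_D: float
    beta_D: float
    m1: float
    u50_1: float
    m2: float
    u50_2: float
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m1 and m2 must be positive")
        if self.u50_1 > self.u50_2:
            raise ValueError("ordering convention requires U50_1 <= U50_2")


def lem_free_energy(m: float, u50: float, u) -> float | np.ndarray:
    """Linear extrapolation model free energy dG = m*(U50 - U), kcal/mol."""
    if m <= 0:
        raise ValueError("m must be positive")
    dg = m * (u50 - np.asarray(u, dtype=float))
    return float(dg) if dg.ndim == 0 else dg


def unfolded_fraction(dg, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """Boltzmann unfolded fraction K/(1+K), K = exp(-dG/RT)."""
    k = np.exp(-np.asarray(dg, dtype=float) / (R_KCAL * temperature_K))
    return k / (1.0 + k)


def two_state_chem_signal(p: TwoStateChemParams, u):
    """Two-state signal X(U); scalar in, scalar out."""
    u = np.asarray(u, dtype=float)
    dg = p.m * (p.u50 - u)
    k = np.exp(-dg / (R_KCAL * p.temperature_K))
    x_n = p.alpha_N + p.beta_N * u
    x_d = p.alpha_D + p.beta_D * u
    out = (x_n + x_d * k) / (1.0 + k)
    return float(out) if out.ndim == 0 else out


def three_state_chem_signal(p: ThreeStateChemParams, u):
    """Sequential three-state signal X(U)."""
    u = np.asarray(u, dtype=float)
    rt = R_KCAL * p.temperature_K
    k1 = np.exp(-p.m1 * (p.u50_1 - u) / rt)
    k2 = np.exp(-p.m2 * (p.u50_2 - u) / rt)
    x_n = p.alpha_N + p.beta_N * u
    x_d = p.alpha_D + p.beta_D * u
    q = 1.0 + k1 + k1 * k2
    out = (x_n + p.alpha_I * k1 + x_d * k1 * k2) / q
    return float(out) if out.ndim == 0 else out


def three_state_populations(p: ThreeStateChemParams, u):
    """Fractional populations (f_N, f_I, f_U); they sum to 1."""
    u = np.asarray(u, dtype=float)
    rt = R_KCAL * p.temperature_K
    k1 = np.exp(-p.m1 * (p.u50_1 - u) / rt)
    k2 = np.exp(-p.m2 * (p.u50_2 - u) / rt)
    q = 1.0 + k1 + k1 * k2
    return 1.0 / q, k1 / q, (k1 * k2) / q


def _two_state_parameters(
    curve: DenaturationCurve,
    fixed: dict | None,
    init: dict | None,
    temperature_K: float,
) -> lmfit.Parameters:
    guess = sigmoid_init(curve.x, curve.y)
    rt = R_KCAL * temperature_K
    m0 = float(np.clip(4.0 * rt * abs(guess["central_slope"]), 0.2, 8.0))
    defaults = {
        "alpha_N": guess["alpha_N"],
        "beta_N": guess["beta_N"],
        "alpha_D": guess["alpha_D"],
        "beta_D": guess["beta_D"],
        "m": m0,
        "u50": guess["midpoint"],
    }
    if init:
        defaults.update(init)
    params = lmfit.Parameters()
    params.add("alpha_N", value=defaults["alpha_N"])
    params.add("beta_N", value=defaults["beta_N"])
    params.add("alpha_D", value=defaults["alpha_D"])
    params.add("beta_D", value=defaults["beta_D"])
    params.add("m", value=defaults["m"], min=1e-6)
    params.add("u50", value=max(defaults["u50"], 1e-6), min=0.0)
    for name, value in (fixed or {}).items():
        params[name].set(value=value, vary=False)
    return params


def fit_two_state_chem(
    curve: DenaturationCurve,
    fixed: dict | None = None,
    init: dict | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
) -> FitResult:
    """Fit the two-state LEM model to a denaturant curve.

    Initial guesses are derived from the data when ``init`` is absent
    (baselines from the x-range tails, midpoint from the half-amplitude
    crossing). ``fixed`` pins parameters by name. The result carries an
    ``unreliable_denatured_baseline`` flag when fewer than two points
    lie past the transition (unfolded fraction > 0.9), and the derived
    ``dG_water = m*u50`` in ``meta``.
    """
    if curve.axis_kind != "denaturant":
        raise ValueError("fit_two_state_chem expects a denaturant-axis curve")
    if len(curve) < 7:
        raise ValueError("need at least 7 points spanning both baselines")

    params = _two_state_parameters(curve, fixed, init, temperature_K)

    def residual(p):
        model = TwoStateChemParams(
            p["alpha_N"].value, p["beta_N"].value, p["alpha_D"].value,
            p["beta_D"].value, max(p["m"].value, 1e-9), p["u50"].value,
            temperature_K,
        )
        return curve.y - two_state_chem_signal(model, curve.x)

    result = run_fit(residual, params, model="two_state_chem", seed=seed, fixed=fixed or {})
    est = result.params
    frac = unfolded_fraction(
        lem_free_energy(max(est["m"], 1e-9), est["u50"], curve.x), temperature_K
    )
    if int(np.sum(frac > 0.9)) < 2:
        result.flags.append("unreliable_denatured_baseline")
    if not result.converged:
        result.flags.append("non_convergence")
    result.meta.update(
        {
            "temperature_K": temperature_K,
            "dG_water_kcal_mol": est["m"] * est["u50"],
            "reversibility": "equilibrium model; reversibility not verified",
        }
    )
    return result


def fit_three_state_chem(
    curves: DenaturationCurve | Sequence[DenaturationCurve],
    fixed: dict | None = None,
    init: dict | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
) -> FitResult:
    """Fit the sequential three-state model, optionally jointly over probes.

    When a sequence of curves is given, the thermodynamic parameters
    (m1, u50_1, m2, u50_2) are shared while each curve keeps its own
    baselines and intermediate level (suffix ``_c<i>``). Ordering
    U50_1 <= U50_2 is enforced by parameterising the second midpoint as
    ``u50_1 + du50`` with ``du50 >= 0``. If the fitted intermediate
    never exceeds 5% population, an ``intermediate_below_5pct`` flag
    recommending the two-state model is raised.
    """
    if isinstance(curves, DenaturationCurve):
        curves = [curves]
    curves = list(curves)
    for c in curves:
        if c.axis_kind != "denaturant":
            raise ValueError("three-state fit expects denaturant-axis curves")
    if sum(len(c) for c in curves) < 11:
        raise ValueError("need at least 11 points for a three-state fit")

    # per-probe two-state prefits seed the shared thermodynamic block
    prefits = [fit_two_state_chem(c, temperature_K=temperature_K, seed=seed) for c in curves]
    mids = sorted((f["u50"], f["m"]) for f in prefits)
    u50_1_init, m1_init = mids[0]
    u50_2_init, m2_init = mids[-1]
    if len(curves) == 1:
        # single-probe fit: start the two midpoints on either side of the
        # apparent one so the optimiser can split them
        u50_1_init, u50_2_init = 0.8 * u50_1_init, 1.2 * u50_2_init

    params = lmfit.Parameters()
    params.add("m1", value=m1_init, min=1e-6)
    params.add("u50_1", value=max(u50_1_init, 1e-6), min=0.0)
    params.add("m2", value=m2_init, min=1e-6)
    params.add("du50", value=max(u50_2_init - u50_1_init, 1e-3), min=0.0)
    params.add("u50_2", expr="u50_1 + du50")
    for i, (c, f) in enumerate(zip(curves, prefits)):
        params.add(f"alpha_N_c{i}", value=f["alpha_N"])
        params.add(f"beta_N_c{i}", value=f["beta_N"])
        params.add(f"alpha_D_c{i}", value=f["alpha_D"])
        params.add(f"beta_D_c{i}", value=f["beta_D"])
        params.add(f"alpha_I_c{i}", value=0.5 * (f["alpha_N"] + f["alpha_D"]))
    if init:
        for name, value in init.items():
            params[name].set(value=value)
    for name, value in (fixed or {}).items():
        params[name].set(value=value, vary=False)

    def residual(p):
        chunks = []
        for i, c in enumerate(curves):
            model = ThreeStateChemParams(
                p[f"alpha_N_c{i}"].value, p[f"beta_N_c{i}"].value,
                p[f"alpha_I_c{i}"].value, p[f"alpha_D_c{i}"].value,
                p[f"beta_D_c{i}"].value,
                max(p["m1"].value, 1e-9), p["u50_1"].value,
                max(p["m2"].value, 1e-9), p["u50_1"].value + p["du50"].value,
                temperature_K,
            )
            chunks.append(c.y - three_state_chem_signal(model, c.x))
        return np.concatenate(chunks)

    result = run_fit(residual, params, model="three_state_chem", seed=seed, fixed=fixed or {})

    est = result.params
    grid = np.linspace(min(c.x.min() for c in curves), max(c.x.max() for c in curves), 400)
    probe = ThreeStateChemParams(
        0.0, 0.0, 0.0, 0.0, 0.0,
        max(est["m1"], 1e-9), est["u50_1"], max(est["m2"], 1e-9),
        max(est["u50_2"], est["u50_1"]), temperature_K,
    )
    f_i_max = float(np.max(three_state_populations(probe, grid)[1]))
    result.meta["max_intermediate_population"] = f_i_max

    # model selection: the intermediate is unidentifiable when it never
    # gets populated, or when the nested two-state fits already explain
    # the data (no meaningful SSR improvement -> spurious intermediate)
    ssr_two = sum(f.ssr for f in prefits)
    amp2 = sum(c.amplitude**2 for c in curves) / len(curves)
    ssr_floor = sum(len(c) for c in curves) * 1e-16 * amp2
    no_improvement = ssr_two <= ssr_floor or result.ssr > 0.9 * ssr_two
    result.meta["ssr_two_state"] = ssr_two
    if f_i_max < 0.05 or no_improvement:
        result.flags.append("intermediate_unresolved")
        result.flags.append("two_state_recommended")
    if not result.converged:
        result.flags.append("non_convergence")
    result.meta["temperature_K"] = temperature_K
    return result
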