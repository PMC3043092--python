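"""Differential scanning calorimetry: excess heat capacity models and fits.

For a two-state transition with van't Hoff enthalpy dH at midpoint Tm,
the baseline-subtracted excess heat capacity is

    Cp_ex(T) = dH^2 / (R T^2) * K / (1 + K)^2,   K = exp(-dG/RT),
    dG = dH * (1 - T/Tm),

whose integral over temperature equals dH exactly. For a sequential
three-state scheme N <-> I <-> U the excess heat capacity is the
analytic temperature derivative of the ensemble-average enthalpy
<H> = (K1 H1 + K1 K2 (H1+H2)) / Q with Q = 1 + K1 + K1 K2:

    Cp_ex = (M Q - N^2) / (R T^2 Q^2),
    N = K1 H1 + K1 K2 (H1+H2),  M = K1 H1^2 + K1 K2 (H1+H2)^2,

which collapses to the two-state expression when K2 -> 0.

An overall amplitude ``scale`` multiplies the model; it absorbs partial
irreversibility (re-heating scans of partly aggregated material show
the same Tmax with a proportionally smaller calorimetric enthalpy). The
van't Hoff enthalpy comes from the endotherm shape, the calorimetric
enthalpy from trapezoidal integration, and their ratio is the usual
two-state diagnostic (ratio ~ 1 for a reversible two-state transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import find_peaks

from .constants import CELSIUS_OFFSET, R_KCAL
from .curves import DenaturationCurve
from .fitting import FitResult, run_fit

__all__ = ["DSCTransition", "DSCParams", "dsc_excess_cp", "fit_dsc"]


@dataclass
class DSCTransition:
    tm_C: float
    dH: float  # van't Hoff enthalpy, kcal/mol

    def __post_init__(self) -> None:
        if self.dH <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")
        if self.tm_C + CELSIUS_OFFSET <= 0:
            raise ValueError("Tm must be above 0 K")


@dataclass
class DSCParams:
    """One or two sequential transitions plus an overall amplitude."""

    transitions: list[DSCTransition] = field(default_factory=list)
    model_kind: str = "two_state"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.model_kind not in ("two_state", "sequential_three_state"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        need = 1 if self.model_kind == "two_state" else 2
        if len(self.transitions) != need:
            raise ValueError(f"{self.model_kind} needs {need} transition(s)")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


def dsc_excess_cp(p: DSCParams, t_C):
    """Excess heat capacity (kcal mol^-1 K^-1) at Celsius temperature(s)."""
    t_K = np.asarray(t_C, dtype=float) + CELSIUS_OFFSET
    rt = R_KCAL * t_K
    if p.model_kind == "two_state":
        tr = p.transitions[0]
        k = np.exp(-tr.dH * (1.0 - t_K / (tr.tm_C + CELSIUS_OFFSET)) / rt)
        cp = tr.dH**2 / (R_KCAL * t_K**2) * k / (1.0 + k) ** 2
    else:
        t1, t2 = p.transitions
        k1 = np.exp(-t1.dH * (1.0 - t_K / (t1.tm_C + CELSIUS_OFFSET)) / rt)
        k2 = np.exp(-t2.dH * (1.0 - t_K / (t2.tm_C + CELSIUS_OFFSET)) / rt)
        h1, h12 = t1.dH, t1.dH + t2.dH
        q = 1.0 + k1 + k1 * k2
        n = k1 * h1 + k1 * k2 * h12
        m = k1 * h1**2 + k1 * k2 * h12**2
        cp = (m * q - n**2) / (R_KCAL * t_K**2 * q**2)
    cp = p.scale * cp
    return float(cp) if cp.ndim == 0 else cp


def calorimetric_enthalpy(trace: DenaturationCurve) -> float:
    """dH_cal: trapezoidal integral of the excess heat capacity, kcal/mol."""
    return float(np.trapezoid(trace.y, trace.x))


def _init_transitions(trace: DenaturationCurve, model_kind: str) -> list[DSCTransition]:
    x, y = trace.x, trace.y
    area = max(float(np.trapezoid(y, x)), 1e-6)
    if model_kind == "two_state":
        i = int(np.argmax(y))
        tm = float(x[i])
        dh = float(np.clip(4.0 * R_KCAL * (tm + CELSIUS_OFFSET) ** 2 * y[i] / area, 10.0, 300.0))
        return [DSCTransition(tm, dh)]
    peaks, _ = find_peaks(y, prominence=0.05 * float(y.max()))
    if peaks.size >= 2:
        # the two most prominent lobes
        peaks = peaks[np.argsort(y[peaks])[::-1][:2]]
        tms = sorted(float(x[i]) for i in peaks)
    else:
        i = int(np.argmax(y))
        width = 0.15 * float(x.max() - x.min())
        tms = [float(x[i]) - width, float(x[i]) + width]
    dh_each = float(np.clip(area / 2.0, 10.0, 300.0))
    return [DSCTransition(tm, dh_each) for tm in tms]


def fit_dsc(
    trace: DenaturationCurve,
    model_kind: str = "two_state",
    init: DSCParams | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a two-state or sequential three-state endotherm.

    Expects a baseline-subtracted excess-heat-capacity trace
    (probe ``dsc``, x in degC, y in kcal mol^-1 K^-1). Reports per
    transition (Tm, dH_vH) plus the overall amplitude ``scale``; the
    measured calorimetric enthalpy, the temperature of the heat-capacity
    maximum and the van't Hoff/calorimetric ratio land in ``meta``.

    Raises
    ------
    ValueError
        When a negative lobe deeper than 5% of the peak remains
        (failed chemical-baseline subtraction).
    """
    if trace.probe != "dsc":
        raise ValueError("fit_dsc expects a probe='dsc' trace")
    peak = float(trace.y.max())
    if peak <= 0:
        raise ValueError("endotherm has no positive excess heat capacity")
    if float(trace.y.min()) < -0.05 * peak:
        raise ValueError(
            "negative lobe exceeds 5% of the peak: chemical baseline "
            "subtraction looks wrong"
        )

    transitions = init.transitions if init is not None else _init_transitions(trace, model_kind)
    scale0 = init.scale if init is not None else 1.0

    params = lmfit.Parameters()
    for i, tr in enumerate(transitions, start=1):
        params.add(f"tm{i}_C", value=tr.tm_C)
        params.add(f"dH{i}", value=tr.dH, min=1.0)
    params.add("scale", value=scale0, min=1e-6)

    def residual(p):
        trs = [
            DSCTransition(p[f"tm{i}_C"].value, max(p[f"dH{i}"].value, 1e-6))
            for i in range(1, len(transitions) + 1)
        ]
        trs.sort(key=lambda t: t.tm_C)
        model = DSCParams(trs, model_kind=model_kind, scale=p["scale"].value)
        return trace.y - dsc_excess_cp(model, trace.x)

    result = run_fit(residual, params, model=f"dsc_{model_kind}", seed=seed)

    est = result.params
    n_tr = len(transitions)
    tms = sorted(est[f"tm{i}_C"] for i in range(1, n_tr + 1))
    dh_cal = calorimetric_enthalpy(trace)
    dh_vh = est["dH1"] if n_tr == 1 else sum(est[f"dH{i}"] for i in range(1, n_tr + 1))
    tmax = float(trace.x[int(np.argmax(trace.y))])
    result.meta.update(
        {
            "tm_C_sorted": tms,
            "dH_cal_kcal_mol": dh_cal,
            "dH_vH_kcal_mol": dh_vh,
            "ratio_vH_over_cal": dh_vh / dh_cal if dh_cal else float("nan"),
            "tmax_C": tmax,
        }
    )
    if not result.converged:
        result.flags.append("non_convergence")
    return result
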