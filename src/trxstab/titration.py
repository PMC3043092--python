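"""pH-titration models: single Henderson-Hasselbalch sigmoid and
bell-shaped double transitions, with pKa reliability verdicts.

Single transition (base-10 sigmoid, optional Hill coefficient):

    y(pH) = y_low + (y_high - y_low) / (1 + 10^(n*(pKa - pH)))

Double transition (sum of two sigmoids; opposite-sign amplitudes give
the bell/"bump" shape):

    y(pH) = y0 + A1/(1 + 10^(pKa1 - pH)) + A2/(1 + 10^(pKa2 - pH))

pKa values are invariant to affine rescaling of the signal, so fits
accept raw or normalised data. A fit is reported as unreliable when a
plateau is supported by fewer than two points or its standard error
exceeds half the transition amplitude - mirroring the experimental
practice of withholding pKa values when a baseline is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .curves import DenaturationCurve
from .fitting import FitResult, linear_baseline, run_fit

__all__ = [
    "SingleTransitionParams",
    "DoubleTransitionParams",
    "single_pka_signal",
    "bell_signal",
    "fit_single_pka",
    "fit_double_pka",
]

VERDICTS = ("reliable", "no_acid_baseline", "no_base_baseline", "unidentifiable")


@dataclass
class SingleTransitionParams:
    pka: float
    y_low: float
    y_high: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pka < 14:
            raise ValueError("pKa outside 0-14")
        if not 0 < self.hill_n <= 4:
            raise ValueError("Hill coefficient outside (0, 4]")


@dataclass
class DoubleTransitionParams:
    y0: float
    a1: float
    pka1: float
    a2: float
    pka2: float

    def __post_init__(self) -> None:
        if self.pka1 >= self.pka2:
            raise ValueError("convention requires pKa1 < pKa2")


def single_pka_signal(p: SingleTransitionParams, ph):
    ph = np.asarray(ph, dtype=float)
    out = p.y_low + (p.y_high - p.y_low) / (1.0 + 10.0 ** (p.hill_n * (p.pka - ph)))
    return float(out) if out.ndim == 0 else out


def bell_signal(p: DoubleTransitionParams, ph):
    ph = np.asarray(ph, dtype=float)
    out = (
        p.y0
        + p.a1 / (1.0 + 10.0 ** (p.pka1 - ph))
        + p.a2 / (1.0 + 10.0 ** (p.pka2 - ph))
    )
    return float(out) if out.ndim == 0 else out


def _plateau_support(x: np.ndarray, pka: float, margin: float = 1.0) -> tuple[int, int]:
    return int(np.sum(x <= pka - margin)), int(np.sum(x >= pka + margin))


def fit_single_pka(
    curve: DenaturationCurve,
    vary_hill: bool = False,
    init: dict | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a single-pKa sigmoid to a pH-axis curve.

    ``meta["verdict"]`` is ``reliable`` when both plateaus are supported
    by at least two points (more than one pH unit from the fitted pKa)
    and the plateau standard errors stay below half the amplitude;
    otherwise ``no_acid_baseline`` / ``no_base_baseline``.
    """
    if curve.axis_kind != "pH":
        raise ValueError("fit_single_pka expects a pH-axis curve")
    if len(curve) < 6:
        raise ValueError("need at least 6 points")

    x, y = curve.x, curve.y
    defaults = {
        "pka": float(np.interp(0.5 * (y[0] + y[-1]), *_monotone(x, y))),
        "y_low": float(y[0]),
        "y_high": float(y[-1]),
        "hill_n": 1.0,
    }
    if init:
        defaults.update(init)

    params = lmfit.Parameters()
    params.add("pka", value=float(np.clip(defaults["pka"], 0.5, 13.5)), min=0.0, max=14.0)
    params.add("y_low", value=defaults["y_low"])
    params.add("y_high", value=defaults["y_high"])
    params.add("hill_n", value=defaults["hill_n"], vary=vary_hill, min=0.05, max=4.0)

    def residual(p):
        model = SingleTransitionParams.__new__(SingleTransitionParams)
        model.pka, model.y_low, model.y_high, model.hill_n = (
            p["pka"].value, p["y_low"].value, p["y_high"].value, p["hill_n"].value,
        )
        return y - single_pka_signal(model, x)

    result = run_fit(residual, params, model="single_pka", seed=seed,
                     fixed={} if vary_hill else {"hill_n": 1.0})

    est, err = result.params, result.stderr
    amp = abs(est["y_high"] - est["y_low"])
    n_acid, n_base = _plateau_support(x, est["pka"])
    verdict = "reliable"
    if n_acid < 2 or (err["y_low"] is not None and amp > 0 and err["y_low"] > 0.5 * amp):
        verdict = "no_acid_baseline"
    elif n_base < 2 or (err["y_high"] is not None and amp > 0 and err["y_high"] > 0.5 * amp):
        verdict = "no_base_baseline"
    if verdict != "reliable":
        result.flags.append("missing_baseline")
    # monotone drift with no inflection: midpoint outside the scanned
    # range, plateaus extrapolated far beyond the observed signal span,
    # or a plain straight line explaining the data as well as the sigmoid
    line_resid = y - np.polyval(np.polyfit(x, y, 1), x)
    ssr_line = float(line_resid @ line_resid)
    no_inflection = ssr_line <= max(1.2 * result.ssr, result.ssr + 1e-12)
    if not (x.min() < est["pka"] < x.max()) or amp > 3.0 * float(np.ptp(y)) or no_inflection:
        result.flags.append("non_convergence")
        result.converged = False
        verdict = "unidentifiable"
    result.meta["verdict"] = verdict
    return result


def fit_double_pka(
    curve: DenaturationCurve,
    init: dict | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit the two-transition (bell) model; pKa1 < pKa2 by convention.

    Transitions fitted closer than 0.5 pH units raise an
    ``identifiability`` warning flag (``meta["verdict"]`` becomes
    ``unidentifiable``). Pinning ``a2`` to 0 via ``init``+``fixed`` in
    the parameters nests the single-transition model exactly.
    """
    if curve.axis_kind != "pH":
        raise ValueError("fit_double_pka expects a pH-axis curve")
    if len(curve) < 9:
        raise ValueError("need at least 9 points spanning both transitions")

    x, y = curve.x, curve.y
    span = x.max() - x.min()
    defaults = {
        "y0": float(y[0]),
        "a1": float(y[np.argmax(np.abs(y - y[0]))] - y[0]),
        "pka1": float(x.min() + span / 3.0),
        "a2": float(y[-1] - y[np.argmax(np.abs(y - y[0]))]),
        "pka2": float(x.min() + 2.0 * span / 3.0),
    }
    if init:
        defaults.update(init)

    params = lmfit.Parameters()
    params.add("y0", value=defaults["y0"])
    params.add("a1", value=defaults["a1"])
    params.add("pka1", value=float(np.clip(defaults["pka1"], 0.5, 13.0)), min=0.0, max=14.0)
    params.add("a2", value=defaults["a2"])
    params.add("dpka", value=max(defaults["pka2"] - defaults["pka1"], 0.2), min=0.0)
    params.add("pka2", expr="pka1 + dpka")

    def residual(p):
        model = DoubleTransitionParams.__new__(DoubleTransitionParams)
        model.y0, model.a1, model.pka1 = p["y0"].value, p["a1"].value, p["pka1"].value
        model.a2, model.pka2 = p["a2"].value, p["pka1"].value + p["dpka"].value
        return y - bell_signal(model, x)

    result = run_fit(residual, params, model="double_pka", seed=seed)
    verdict = "reliable"
    if result.params["dpka"] < 0.5:
        result.flags.append("identifiability")
        verdict = "unidentifiable"
    if not result.converged:
        result.flags.append("non_convergence")
    result.meta["verdict"] = verdict
    return result


def _monotone(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(y, x) sorted by y for inverse interpolation of the midpoint."""
    order = np.argsort(y)
    return y[order], x[order]
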