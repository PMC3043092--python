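"""Shared nonlinear least-squares machinery.

All model fits in the package go through :func:`run_fit`, a thin layer
over lmfit's damped least squares (Levenberg-Marquardt) that adds
seeded, jittered multi-starts and a uniform :class:`FitResult` record.
Tie-breaking across restarts is by lowest sum of squared residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np

N_RESTARTS = 5
JITTER_FRACTION = 0.1
FTOL = 1e-12
MAX_NFEV = 20000


@dataclass
class FitResult:
    """Outcome of a nonlinear (or linear) model fit.

    ``params``/``stderr`` hold point estimates and standard errors for
    every parameter (stderr is ``None`` when the covariance could not be
    estimated); ``fixed`` records parameters pinned by the caller;
    ``flags`` collects data-quality warnings such as missing baselines.
    """

    model: str
    params: dict
    stderr: dict
    residuals: np.ndarray
    ssr: float
    converged: bool
    nfev: int
    fixed: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "ssr": self.ssr,
            "converged": self.converged,
            "nfev": self.nfev,
            "fixed": self.fixed,
            "flags": self.flags,
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def run_fit(
    residual_fn,
    params: lmfit.Parameters,
    model: str,
    seed: int = 0,
    n_restarts: int = N_RESTARTS,
    fixed: dict | None = None,
    meta: dict | None = None,
) -> FitResult:
    """Minimise ``residual_fn`` with seeded jittered restarts.

    The first start uses the initial values in ``params``; subsequent
    starts multiply every free parameter by ``1 + N(0, 0.1)`` (seeded),
    and the solution with the lowest SSR wins.
    """
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_restarts)):
        trial = params.copy()
        if attempt > 0:
            for par in trial.values():
                if par.vary and par.expr is None:
                    scale = abs(par.value) if par.value != 0 else 1.0
                    jittered = par.value + scale * JITTER_FRACTION * rng.standard_normal()
                    par.set(value=float(np.clip(jittered, par.min, par.max)))
        try:
            out = lmfit.minimize(
                residual_fn,
                trial,
                method="leastsq",
                ftol=FTOL,
                xtol=FTOL,
                max_nfev=MAX_NFEV,
            )
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError(f"{model}: all fit attempts failed")

    estimates = {name: float(par.value) for name, par in best.params.items()}
    errors = {
        name: (float(par.stderr) if (par.vary or par.expr) and par.stderr is not None else None)
        for name, par in best.params.items()
    }
    return FitResult(
        model=model,
        params=estimates,
        stderr=errors,
        residuals=np.asarray(best.residual, dtype=float),
        ssr=float(best.chisqr),
        converged=bool(best.success),
        nfev=int(best.nfev),
        fixed=dict(fixed or {}),
        flags=[],
        meta=dict(meta or {}),
    )


def linear_baseline(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line through (x, y); constant fallback for < 2 points."""
    if x.size < 2:
        return float(y.mean()), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def sigmoid_init(x: np.ndarray, y: np.ndarray, tail_fraction: float = 0.2):
    """Heuristic initial guesses for a two-baseline sigmoid.

    Baselines come from linear fits to the lowest/highest
    ``tail_fraction`` of the x range, the midpoint from the
    half-amplitude crossing of the baseline-corrected signal, and the
    central slope (per unit amplitude) is returned for transition-width
    guesses.
    """
    n_tail = max(2, int(np.ceil(tail_fraction * x.size)))
    a_lo, b_lo = linear_baseline(x[:n_tail], y[:n_tail])
    a_hi, b_hi = linear_baseline(x[-n_tail:], y[-n_tail:])

    lo = a_lo + b_lo * x
    hi = a_hi + b_hi * x
    denom = hi - lo
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    frac = (y - lo) / denom
    frac = np.clip(frac, -0.5, 1.5)

    # half-amplitude crossing, linearly interpolated
    crossing = None
    for i in range(frac.size - 1):
        if (frac[i] - 0.5) * (frac[i + 1] - 0.5) <= 0 and frac[i] != frac[i + 1]:
            t = (0.5 - frac[i]) / (frac[i + 1] - frac[i])
            crossing = float(x[i] + t * (x[i + 1] - x[i]))
            break
    if crossing is None:
        crossing = float(x[int(np.argmin(np.abs(frac - 0.5)))])

    grad = np.gradient(frac, x)
    idx = int(np.argmin(np.abs(x - crossing)))
    central_slope = float(grad[idx])

    return {
        "alpha_N": a_lo,
        "beta_N": b_lo,
        "alpha_D": a_hi,
        "beta_D": b_hi,
        "midpoint": crossing,
        "central_slope": central_slope,
    }
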