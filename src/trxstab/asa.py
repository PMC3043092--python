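"""Accessible-surface-area bookkeeping and theoretical m-value prediction.

The m-value of chemical denaturation is empirically proportional to the
surface area newly exposed on unfolding. With delta-ASA (angstrom^2)
taken as the difference between the extended (fully unfolded) and
folded states, the GdmCl regression of Myers, Pace and Scholtz gives

    m_theory = 0.859 + 2.2e-4 * delta_ASA_total    [kcal mol^-1 M^-1].

The per-protein ASA tables are consumed as data (they come from a
structure-analysis server, not computed here).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ASATable",
    "MValuePrediction",
    "delta_asa",
    "myers_m_gdmcl",
    "lem_consistency",
    "predict_m_value",
    "MYERS_INTERCEPT",
    "MYERS_SLOPE",
]

#: GdmCl regression coefficients (kcal/mol and kcal mol^-1 M^-1 A^-2).
MYERS_INTERCEPT = 0.859
MYERS_SLOPE = 2.2e-4


@dataclass
class ASATable:
    """Per-protein folded/extended polar and non-polar ASA (angstrom^2)."""

    protein: str
    folded_nonpolar: float
    folded_polar: float
    extended_nonpolar: float
    extended_polar: float
    hbond_count: int = 0

    def __post_init__(self) -> None:
        for val in (
            self.folded_nonpolar,
            self.folded_polar,
            self.extended_nonpolar,
            self.extended_polar,
        ):
            if val <= 0:
                raise ValueError("ASA values must be positive")
        if self.extended_nonpolar < self.folded_nonpolar:
            raise ValueError("extended non-polar ASA below folded value")
        if self.extended_polar < self.folded_polar:
            raise ValueError("extended polar ASA below folded value")


@dataclass
class MValuePrediction:
    protein: str
    delta_asa_nonpolar: float
    delta_asa_polar: float
    delta_asa_total: float
    m_theory: float | None = None


def delta_asa(table: ASATable) -> MValuePrediction:
    """Per-polarity delta-ASA = extended - folded; total is their sum."""
    d_np = table.extended_nonpolar - table.folded_nonpolar
    d_p = table.extended_polar - table.folded_polar
    return MValuePrediction(
        protein=table.protein,
        delta_asa_nonpolar=d_np,
        delta_asa_polar=d_p,
        delta_asa_total=d_np + d_p,
    )


def myers_m_gdmcl(
    delta_asa_total: float,
    intercept: float = MYERS_INTERCEPT,
    slope: float = MYERS_SLOPE,
) -> float:
    """Theoretical GdmCl m-value (kcal mol^-1 M^-1) from total delta-ASA."""
    if delta_asa_total <= 0:
        raise ValueError("delta-ASA must be positive")
    return intercept + slope * delta_asa_total


def lem_consistency(m: float, u50: float, dg_reported: float) -> float:
    """Relative deviation |m*U50 - dG_reported| / dG_reported.

    A quick self-consistency check between a reported unfolding free
    energy and the product of the fitted LEM slope and midpoint.
    """
    if m <= 0 or u50 <= 0 or dg_reported <= 0:
        raise ValueError("all inputs must be positive")
    return abs(m * u50 - dg_reported) / dg_reported


def predict_m_value(table: ASATable) -> MValuePrediction:
    """delta-ASA bookkeeping plus the Myers m-value in one call."""
    pred = delta_asa(table)
    pred.m_theory = myers_m_gdmcl(pred.delta_asa_total)
    return pred
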