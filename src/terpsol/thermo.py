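"""Apparent dissolution thermodynamics from the van't Hoff relation.

ln x is regressed on (1/T − 1/Thm), with Thm the harmonic mean of the
experimental temperatures.  The slope and intercept give the apparent
standard quantities of solution:

* ΔsolH⁰ = −R·slope          (J/mol)
* ΔsolG⁰ = −R·Thm·intercept  (J/mol)
* ΔsolS⁰ = (ΔsolH⁰ − ΔsolG⁰)/Thm

and the dimensionless weighting coefficients δH = |ΔsolH⁰| / (|ΔsolH⁰| +
|Thm·ΔsolS⁰|), δTS = 1 − δH, which apportion the Gibbs energy between its
enthalpic and entropic contributions.  Recentring the regressor at 1/Thm
leaves the slope untouched and makes the intercept directly proportional
to ΔsolG⁰.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import SolubilityDataset
from .models import R_GAS

__all__ = [
    "ThermoSummary",
    "harmonic_mean_temperature",
    "vanthoff_regression",
    "solution_thermodynamics",
    "enthalpy_entropy_weights",
    "analyze_dataset",
]


def harmonic_mean_temperature(Ts: Sequence[float]) -> float:
    """Harmonic mean n / Σ(1/Ti) of the experimental temperatures."""
    T = np.asarray(Ts, dtype=float)
    if T.size == 0:
        raise ValueError("need at least one temperature")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    return float(T.size / np.sum(1.0 / T))


def vanthoff_regression(dataset: SolubilityDataset) -> tuple[float, float]:
    """OLS of ln x_exp on (1/T − 1/Thm); returns (slope in K, intercept)."""
    if len(dataset) < 3:
        raise ValueError("need at least 3 points for the van't Hoff regression")
    T = dataset.T
    if np.ptp(T) == 0:
        raise ValueError("all temperatures equal; regression is degenerate")
    Thm = harmonic_mean_temperature(T)
    u = 1.0 / T - 1.0 / Thm
    X = np.column_stack([np.ones_like(u), u])
    coef, *_ = np.linalg.lstsq(X, np.log(dataset.x_exp), rcond=None)
    return float(coef[1]), float(coef[0])


def solution_thermodynamics(
    slope: float, intercept: float, Thm: float
) -> tuple[float, float, float]:
    """(ΔsolH⁰, ΔsolG⁰, ΔsolS⁰) in J/mol, J/mol, J/(mol K) from the regression."""
    if Thm <= 0:
        raise ValueError("Thm must be positive")
    dH = -R_GAS * slope
    dG = -R_GAS * Thm * intercept
    dS = (dH - dG) / Thm
    return dH, dG, dS


def enthalpy_entropy_weights(dH: float, dS: float, Thm: float) -> tuple[float, float]:
    """(δH, δTS) = (|ΔH|, |Thm·ΔS|) / (|ΔH| + |Thm·ΔS|)."""
    a, b = abs(dH), abs(Thm * dS)
    if a + b == 0:
        raise ValueError("both contributions are zero; weights undefined")
    return a / (a + b), b / (a + b)


@dataclass(frozen=True)
class ThermoSummary:
    """Apparent dissolution thermodynamics of one solvent system."""

    system: str
    Thm: float
    slope: float
    intercept: float
    dG_kJ: float
    dH_kJ: float
    dS_J_per_K: float
    deltaH_w: float
    deltaTS_w: float

    def row(self) -> dict:
        return {
            "system": self.system,
            "intercept": round(self.intercept, 4),
            "slope": round(self.slope, 4),
            "dG_kJ_mol": round(self.dG_kJ, 4),
            "dH_kJ_mol": round(self.dH_kJ, 4),
            "dS_J_mol_K": round(self.dS_J_per_K, 4),
            "delta_H": round(self.deltaH_w, 4),
            "delta_TS": round(self.deltaTS_w, 4),
        }


def analyze_dataset(dataset: SolubilityDataset) -> ThermoSummary:
    """Full van't Hoff analysis of one dataset."""
    Thm = harmonic_mean_temperature(dataset.T)
    slope, intercept = vanthoff_regression(dataset)
    dH, dG, dS = solution_thermodynamics(slope, intercept, Thm)
    wH, wTS = enthalpy_entropy_weights(dH, dS, Thm)
    return ThermoSummary(
        system=dataset.label,
        Thm=Thm,
        slope=slope,
        intercept=intercept,
        dG_kJ=dG / 1000.0,
        dH_kJ=dH / 1000.0,
        dS_J_per_K=dS,
        deltaH_w=wH,
        deltaTS_w=wTS,
    )
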