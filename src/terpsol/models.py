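"""Solubility-temperature models and activity-coefficient models.

Forward evaluation x(T; params) for every correlation used in the analysis:

* modified Apelblat: ln x = A + B/T + C ln T
* Buchowski λh:      ln(1 + λ(1−x)/x) = λh(1/T − 1/Tm), inverted in closed form
* van't Hoff:        ln x = A + B/T
* NRTL and UNIQUAC activity coefficients, closed through the simplified
  solid-liquid-equilibrium relation ln(x·γ1) = −(ΔfusH/R)(1/T − 1/Tm)
  (heat-capacity terms neglected)
* modified Wilson and Wilson–van't Hoff mixing rules for binary solvents.

All temperatures are in K, energies in J/mol, compositions are mole
fractions except the Wilson rules' w1/w2 which are solvent mass fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .data import SoluteProperties

__all__ = [
    "R_GAS",
    "ApelblatParams",
    "LambdaHParams",
    "VantHoffParams",
    "NRTLParams",
    "UNIQUACParams",
    "UNIQUACStructure",
    "WilsonParams",
    "WilsonVantHoffParams",
    "apelblat_x",
    "lambda_h_x",
    "vanthoff_x",
    "ideal_solubility",
    "nrtl_gamma",
    "uniquac_gamma",
    "uniquac_structure_from_groups",
    "UNIFAC_RQ",
    "MOLECULE_GROUPS",
    "structure_for",
    "sle_solve_x",
    "sle_solve_x_grid",
    "modified_wilson_xm",
    "wilson_vanthoff_xm",
]

#: Gas constant, J mol^-1 K^-1 (value used throughout the source analysis).
R_GAS = 8.314


class ModelError(ValueError):
    """Invalid model input or parameters."""


class ConvergenceError(RuntimeError):
    """An iterative solve failed; carries the last iterate and residual."""

    def __init__(self, msg: str, last: float, residual: float):
        super().__init__(msg)
        self.last = last
        self.residual = residual


@dataclass(frozen=True)
class ApelblatParams:
    A: float
    B: float
    C: float


@dataclass(frozen=True)
class LambdaHParams:
    lam: float
    h: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ModelError(f"lambda must be positive, got {self.lam}")


@dataclass(frozen=True)
class VantHoffParams:
    A: float
    B: float


@dataclass(frozen=True)
class NRTLParams:
    """NRTL interaction energies Δg12, Δg21 (J/mol); α is fixed at 0.3."""

    dg12: float
    dg21: float
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ModelError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class UNIQUACParams:
    du12: float
    du21: float


@dataclass(frozen=True)
class UNIQUACStructure:
    """Pure-component volume (r) and surface (q) parameters; z defaults to 10."""

    r: tuple[float, float]
    q: tuple[float, float]
    z: float = 10.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.r) or any(v <= 0 for v in self.q):
            raise ModelError("r and q must be positive")


@dataclass(frozen=True)
class WilsonParams:
    lam12: float
    lam21: float


@dataclass(frozen=True)
class WilsonVantHoffParams:
    lam12: float
    lam21: float
    A1: float
    B1: float
    A2: float
    B2: float


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ModelError("temperature must be positive")
    return T


def apelblat_x(params: ApelblatParams, T):
    """Modified Apelblat solubility exp(A + B/T + C ln T)."""
    T = _check_T(T)
    return np.exp(params.A + params.B / T + params.C * np.log(T))


def vanthoff_x(params: VantHoffParams, T):
    """van't Hoff solubility exp(A + B/T)."""
    T = _check_T(T)
    return np.exp(params.A + params.B / T)


def lambda_h_x(params: LambdaHParams, T, Tm: float):
    """Closed-form inversion of the Buchowski λh relation.

    From ln(1 + λ(1−x)/x) = λh(1/T − 1/Tm):
    x = λ / (exp(λh(1/T − 1/Tm)) − 1 + λ).  At T = Tm this is exactly 1;
    λ = 1 reduces to the ideal van't Hoff form exp(−h(1/T − 1/Tm)).
    """
    T = _check_T(T)
    if np.any(T > Tm):
        raise ModelError("T must not exceed the melting temperature")
    lam, h = params.lam, params.h
    return lam / (np.expm1(lam * h * (1.0 / T - 1.0 / Tm)) + lam)


def ideal_solubility(T, solute: SoluteProperties):
    """Ideal-solution solubility exp(−(ΔfusH/R)(1/T − 1/Tm)).

    The simplified Schröder–van Laar relation with the ΔCp terms neglected;
    equals 1 at the melting point.
    """
    T = _check_T(T)
    if np.any(T > solute.Tm):
        raise ModelError("T must not exceed the melting temperature")
    return np.exp(-(solute.dHfus / R_GAS) * (1.0 / T - 1.0 / solute.Tm))


def nrtl_gamma(x1, T, params: NRTLParams):
    """NRTL activity coefficients (γ1, γ2) for a binary mixture.

    τij = Δgij/(RT), Gij = exp(−α τij); the two-parameter form with the
    non-randomness factor fixed.
    """
    T = _check_T(T)
    x1 = np.asarray(x1, dtype=float)
    if np.any((x1 < 0) | (x1 > 1)):
        raise ModelError("x1 must lie in [0, 1]")
    x2 = 1.0 - x1
    t12 = params.dg12 / (R_GAS * T)
    t21 = params.dg21 / (R_GAS * T)
    G12 = np.exp(-params.alpha * t12)
    G21 = np.exp(-params.alpha * t21)
    ln_g1 = x2**2 * (t21 * (G21 / (x1 + x2 * G21)) ** 2 + t12 * G12 / (x2 + x1 * G12) ** 2)
    ln_g2 = x1**2 * (t12 * (G12 / (x2 + x1 * G12)) ** 2 + t21 * G21 / (x1 + x2 * G21) ** 2)
    return np.exp(ln_g1), np.exp(ln_g2)


#: Standard UNIFAC-style subgroup volume (R) and surface (Q) constants used
#: to build UNIQUAC pure-component structural parameters.
UNIFAC_RQ: dict[str, tuple[float, float]] = {
    "CH3": (0.9011, 0.848),
    "CH2": (0.6744, 0.540),
    "CH": (0.4469, 0.228),
    "C": (0.2195, 0.000),
    "CH2=CH": (1.3454, 1.176),
    "CH=CH": (1.1167, 0.867),
    "CH2=C": (1.1173, 0.988),
    "CH=C": (0.8886, 0.676),
    "C=C": (0.6605, 0.485),
    "ACH": (0.5313, 0.400),
    "AC": (0.3652, 0.120),
    "ACCH3": (1.2663, 0.968),
    "ACCH2": (1.0396, 0.660),
    "ACCH": (0.8121, 0.348),
    "COOH": (1.3013, 1.224),
}

#: First-order group assignments for the study's molecules.
MOLECULE_GROUPS: dict[str, dict[str, int]] = {
    # tricyclic diterpenoid acid: aromatic ring fused at two positions,
    # isopropyl substituent, two angular methyls, carboxyl at C4
    "dehydroabietic acid": {
        "CH3": 4, "CH2": 5, "CH": 2, "C": 2, "COOH": 1, "ACH": 3, "AC": 3,
    },
    # bicyclo[3.1.1]hept-2-ene skeleton, trisubstituted double bond
    "(-)-alpha-pinene": {"CH3": 3, "CH2": 2, "CH": 2, "C": 1, "CH=C": 1},
    "p-cymene": {"CH3": 2, "ACH": 4, "ACCH3": 1, "ACCH": 1},
    # bicyclic sesquiterpene: exocyclic methylene + trisubstituted ring alkene
    "(-)-beta-caryophyllene": {
        "CH3": 3, "CH2": 5, "CH": 2, "C": 1, "CH2=C": 1, "CH=C": 1,
    },
}


def uniquac_structure_from_groups(
    group_counts: Mapping[str, int | float],
    table: Mapping[str, tuple[float, float]] = UNIFAC_RQ,
) -> tuple[float, float]:
    """Pure-component (r, q) from a group inventory: r = Σ ν R_i, q = Σ ν Q_i."""
    if not group_counts:
        raise ModelError("at least one group required")
    r = q = 0.0
    for g, n in group_counts.items():
        if n < 0:
            raise ModelError(f"negative count for group {g!r}")
        if g not in table:
            raise KeyError(f"unknown group {g!r}")
        Ri, Qi = table[g]
        r += n * Ri
        q += n * Qi
    return r, q


def structure_for(
    solute_name: str, solvent_names: tuple[str, ...], solvent_fractions=None
) -> UNIQUACStructure:
    """UNIQUAC structure for a solute/solvent pair from the shipped group table.

    A binary mixed solvent is treated as one pseudo-component whose r and q
    are the mole-fraction-weighted means of the two pure solvents.
    """
    r1, q1 = uniquac_structure_from_groups(MOLECULE_GROUPS[solute_name])
    rqs = [uniquac_structure_from_groups(MOLECULE_GROUPS[n]) for n in solvent_names]
    if len(rqs) == 1:
        r2, q2 = rqs[0]
    else:
        f = solvent_fractions if solvent_fractions is not None else (0.5, 0.5)
        r2 = f[0] * rqs[0][0] + f[1] * rqs[1][0]
        q2 = f[0] * rqs[0][1] + f[1] * rqs[1][1]
    return UNIQUACStructure(r=(r1, r2), q=(q1, q2))


def uniquac_gamma(x1, T, params: UNIQUACParams, structure: UNIQUACStructure):
    """UNIQUAC activity coefficients (γ1, γ2) for a binary mixture.

    Combinatorial part from the volume/surface fractions (φ, θ) and the
    li = (z/2)(ri − qi) − (ri − 1) terms; residual part from τij =
    exp(−Δuij/(RT)).
    """
    T = _check_T(T)
    x1 = np.asarray(x1, dtype=float)
    x2 = 1.0 - x1
    (r1, r2), (q1, q2), z = structure.r, structure.q, structure.z
    t12 = np.exp(-params.du12 / (R_GAS * T))
    t21 = np.exp(-params.du21 / (R_GAS * T))

    sr = x1 * r1 + x2 * r2
    sq = x1 * q1 + x2 * q2
    # φi/xi and θi/φi stay finite as xi -> 0, so work with ratios
    phi1_x, phi2_x = r1 / sr, r2 / sr
    th1, th2 = x1 * q1 / sq, x2 * q2 / sq
    l1 = z / 2.0 * (r1 - q1) - (r1 - 1.0)
    l2 = z / 2.0 * (r2 - q2) - (r2 - 1.0)
    sum_l = x1 * l1 + x2 * l2

    # combinatorial (θi/φi = (qi/ri)·sr/sq, finite at the composition limits)
    th_over_phi1 = (q1 / r1) * sr / sq
    th_over_phi2 = (q2 / r2) * sr / sq
    ln_g1c = np.log(phi1_x) + z / 2.0 * q1 * np.log(th_over_phi1) + l1 - phi1_x * sum_l
    ln_g2c = np.log(phi2_x) + z / 2.0 * q2 * np.log(th_over_phi2) + l2 - phi2_x * sum_l
    # residual
    s1 = th1 + th2 * t21
    s2 = th2 + th1 * t12
    ln_g1r = q1 * (1.0 - np.log(s1) - th1 / s1 - th2 * t12 / s2)
    ln_g2r = q2 * (1.0 - np.log(s2) - th2 / s2 - th1 * t21 / s1)
    return np.exp(ln_g1c + ln_g1r), np.exp(ln_g2c + ln_g2r)


def sle_solve_x(
    gamma1: Callable[[float, float], float],
    T: float,
    solute: SoluteProperties,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Solve x·γ1(x, T) = x_ideal(T) by damped fixed-point iteration.

    ``gamma1`` maps (x1, T) to the solute activity coefficient.  Iterates
    x ← ½(x + x_ideal/γ1(x)) until successive iterates differ by less than
    ``tol``; raises :class:`ConvergenceError` after ``max_iter`` sweeps.
    """
    x_id = float(ideal_solubility(T, solute))
    x = x_id
    for _ in range(max_iter):
        x_new = 0.5 * (x + x_id / float(gamma1(x, T)))
        x_new = min(max(x_new, 1e-12), 1.0 - 1e-12)
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    resid = x * float(gamma1(x, T)) - x_id
    raise ConvergenceError(
        f"SLE fixed point did not converge at T={T} K", last=x, residual=resid
    )


def sle_solve_x_grid(
    gamma1,
    T,
    solute: SoluteProperties,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Vectorised :func:`sle_solve_x` over a temperature grid.

    ``gamma1`` must accept array-valued (x1, T).  Raises
    :class:`ConvergenceError` if any grid point fails to converge.
    """
    T = _check_T(T)
    x_id = np.asarray(ideal_solubility(T, solute), dtype=float)
    x = x_id.copy()
    for _ in range(max_iter):
        x_new = 0.5 * (x + x_id / np.asarray(gamma1(x, T), dtype=float))
        x_new = np.clip(x_new, 1e-12, 1.0 - 1e-12)
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x = x_new
    resid = float(np.max(np.abs(x * np.asarray(gamma1(x, T)) - x_id)))
    raise ConvergenceError("SLE fixed point did not converge on grid", last=float(x[0]), residual=resid)


def _wilson_form(lam12, lam21, w1, ln_x1, ln_x2):
    w1 = np.asarray(w1, dtype=float)
    if np.any((w1 < 0) | (w1 > 1)):
        raise ModelError("w1 must lie in [0, 1]")
    w2 = 1.0 - w1
    d1 = w1 + w2 * lam12
    d2 = w2 + w1 * lam21
    if np.any(np.isclose(d1, 0.0)) or np.any(np.isclose(d2, 0.0)):
        raise ModelError("Wilson denominator vanishes for these parameters")
    neg_ln_xm = 1.0 - w1 * (1.0 + ln_x1) / d1 - w2 * (1.0 + ln_x2) / d2
    with np.errstate(over="ignore"):  # absurd params give inf, rejected upstream
        return np.exp(-neg_ln_xm)


def modified_wilson_xm(params: WilsonParams, w1, x1_pure, x2_pure):
    """Modified Wilson mixing rule for solubility in a binary solvent.

    −ln xm = 1 − w1(1 + ln x1)/(w1 + w2 λ12) − w2(1 + ln x2)/(w2 + w1 λ21),
    with x1, x2 the solubilities in the two pure solvents at the same T.
    Reduces exactly to the pure-solvent solubility at w1 = 1 or w1 = 0.
    """
    x1p = np.asarray(x1_pure, dtype=float)
    x2p = np.asarray(x2_pure, dtype=float)
    if np.any((x1p <= 0) | (x1p >= 1)) or np.any((x2p <= 0) | (x2p >= 1)):
        raise ModelError("pure-solvent solubilities must lie in (0, 1)")
    return _wilson_form(params.lam12, params.lam21, w1, np.log(x1p), np.log(x2p))


def wilson_vanthoff_xm(params: WilsonVantHoffParams, w1, T):
    """Wilson mixing rule with van't Hoff pure-solvent solubility ln xi = Ai + Bi/T."""
    T = _check_T(T)
    ln_x1 = params.A1 + params.B1 / T
    ln_x2 = params.A2 + params.B2 / T
    return _wilson_form(params.lam12, params.lam21, w1, ln_x1, ln_x2)
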