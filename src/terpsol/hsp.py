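"""Hansen solubility parameters by the Fedors group-contribution method.

Each functional group contributes a cohesive energy E (J/mol) and a molar
volume V (cm³/mol, negative for ring/branch corrections); the total
solubility parameter of a molecule is δ = sqrt(Σ νE / Σ νV) in MPa^0.5.
The smaller the mismatch Δδt = |δ_solvent − δ_solute|, the better the
expected mutual solubility ("like dissolves like" screening).

The module ships the Fedors constants for the groups present in
dehydroabietic acid and the study's terpene solvent δ values.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FEDORS_GROUPS",
    "SOLVENT_DELTAS",
    "hsp_from_groups",
    "mixed_solvent_delta",
    "delta_mismatch",
    "mismatch_table",
]

#: Fedors constants per group occurrence: (E in J/mol, V in cm³/mol).
FEDORS_GROUPS: dict[str, tuple[float, float]] = {
    "CH3": (4707.0, 33.5),
    "CH2": (4937.12, 16.1),
    "CH": (3430.88, -1.0),
    "C": (1464.4, -19.2),
    "COOH": (27614.4, 28.5),
    "benzene ring": (31923.92, 33.4),
    "ring": (1046.0, 16.0),
}

#: Total solubility parameter δt (MPa^0.5) of the study's solvents.
SOLVENT_DELTAS: dict[str, float] = {
    "(-)-alpha-pinene": 17.6069,
    "p-cymene": 18.0516,
    "(-)-beta-caryophyllene": 17.7463,
}


def hsp_from_groups(
    group_counts: Mapping[str, int | float],
    table: Mapping[str, tuple[float, float]] = FEDORS_GROUPS,
) -> float:
    """Total solubility parameter δ = sqrt(Σ count·E / Σ count·V) in MPa^0.5."""
    if not group_counts:
        raise ValueError("at least one group required")
    E = V = 0.0
    for g, n in group_counts.items():
        if g not in table:
            raise KeyError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError(f"negative count for group {g!r}")
        e, v = table[g]
        E += n * e
        V += n * v
    if V <= 0:
        raise ValueError(f"total molar volume must be positive, got {V}")
    return float(np.sqrt(E / V))


def mixed_solvent_delta(deltas: Sequence[float], fractions: Sequence[float]) -> float:
    """Weighted arithmetic mean Σ f_i δ_i of pure-solvent parameters.

    ``fractions`` must be non-negative and sum to 1 (mass-fraction basis for
    the study's equal-mass mixtures; at w = 0.5 the averaging basis is
    indistinguishable).
    """
    d = np.asarray(deltas, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if d.shape != f.shape:
        raise ValueError("deltas and fractions must have equal length")
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {f.sum()}")
    if np.any(d <= 0):
        raise ValueError("solubility parameters must be positive")
    return float(np.dot(f, d))


def delta_mismatch(delta_solute: float, delta_solvent: float) -> float:
    """Δδt = |δ_solvent − δ_solute| in MPa^0.5."""
    if delta_solute <= 0 or delta_solvent <= 0:
        raise ValueError("solubility parameters must be positive")
    return abs(delta_solvent - delta_solute)


def mismatch_table(delta_solute: float) -> dict[str, tuple[float, float]]:
    """(δ, Δδt) for the three pure solvents and their equal-mass binaries."""
    out: dict[str, tuple[float, float]] = {}
    for name, d in SOLVENT_DELTAS.items():
        out[name] = (d, delta_mismatch(delta_solute, d))
    pairs = [
        ("p-cymene", "(-)-beta-caryophyllene"),
        ("p-cymene", "(-)-alpha-pinene"),
        ("(-)-alpha-pinene", "(-)-beta-caryophyllene"),
    ]
    for a, b in pairs:
        d = mixed_solvent_delta([SOLVENT_DELTAS[a], SOLVENT_DELTAS[b]], [0.5, 0.5])
        out[f"{a} + {b}"] = (d, delta_mismatch(delta_solute, d))
    return out
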