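"""Data model and I/O for solid-liquid-equilibrium solubility experiments.

A solubility experiment is a set of (temperature, mole-fraction solubility)
records for one solvent system — a pure solvent or a binary solvent mixture
characterised by the mass fraction ``w1`` of its first component.  Datasets
are exchanged as plain CSV with columns ``system, w1, T_K, x_exp``.

The module also ships the study's measured data for dehydroabietic acid
(C20H28O2) in three terpene monosolvents ((−)-α-pinene, p-cymene,
(−)-β-caryophyllene), three equal-mass binary mixtures of those solvents,
and three composition scans, together with the solute's solid-state
properties, via :func:`builtin_fixtures` and :data:`DEHYDROABIETIC_ACID`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "SolubilityPoint",
    "SolventSystem",
    "SolubilityDataset",
    "SoluteProperties",
    "MOLAR_MASSES",
    "DEHYDROABIETIC_ACID",
    "mole_fraction_solubility",
    "solvent_mass_fraction",
    "load_dataset",
    "save_dataset",
    "builtin_fixtures",
]

#: Molar masses in g/mol from the molecular formulas (not printed in the
#: source tables): dehydroabietic acid C20H28O2, (−)-α-pinene C10H16,
#: p-cymene C10H14, (−)-β-caryophyllene C15H24.
MOLAR_MASSES: dict[str, float] = {
    "dehydroabietic acid": 300.442,
    "(-)-alpha-pinene": 136.234,
    "p-cymene": 134.218,
    "(-)-beta-caryophyllene": 204.351,
}


class DataError(ValueError):
    """Invalid solubility data (bad value, bad file, broken invariant)."""


@dataclass(frozen=True)
class SolubilityPoint:
    """One equilibrium record: absolute temperature and mole-fraction solubility.

    ``w1`` optionally carries a per-point solvent composition; it is only
    set for composition-scan datasets where each record has its own mixed
    solvent make-up.
    """

    T: float
    x_exp: float
    w1: float | None = None

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise DataError(f"temperature must be positive, got {self.T}")
        if not 0 < self.x_exp < 1:
            raise DataError(f"mole fraction must lie in (0, 1), got {self.x_exp}")
        if self.w1 is not None and not 0 <= self.w1 <= 1:
            raise DataError(f"mass fraction w1 must lie in [0, 1], got {self.w1}")


@dataclass(frozen=True)
class SolventSystem:
    """A pure solvent or a binary solvent mixture.

    ``w1`` is the mass fraction of the first named solvent (1.0 for a pure
    solvent, ``None`` for composition scans where w1 varies per point).
    """

    names: tuple[str, ...]
    w1: float | None = 1.0
    molar_masses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.names) <= 2:
            raise DataError("a solvent system has one or two components")
        if len(self.names) == 1 and self.w1 != 1.0:
            raise DataError("w1 must be 1 for a monosolvent")
        if self.w1 is not None and not 0 <= self.w1 <= 1:
            raise DataError(f"w1 must lie in [0, 1], got {self.w1}")
        if self.molar_masses and len(self.molar_masses) != len(self.names):
            raise DataError("one molar mass per solvent component required")
        if any(m <= 0 for m in self.molar_masses):
            raise DataError("molar masses must be positive")

    @property
    def label(self) -> str:
        if len(self.names) == 1:
            return self.names[0]
        if self.w1 is None:
            return f"{self.names[0]} (w1 scan) + {self.names[1]}"
        return f"{self.names[0]} (w1={self.w1:g}) + {self.names[1]}"

    @property
    def is_binary(self) -> bool:
        return len(self.names) == 2


@dataclass(frozen=True)
class SolubilityDataset:
    """An ordered set of solubility records for one solvent system."""

    system: SolventSystem
    points: tuple[SolubilityPoint, ...]
    pressure_kPa: float = 101.3

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: (p.w1 if p.w1 is not None else -1.0, p.T)))
        keys = [(p.w1, p.T) for p in pts]
        for a, b in zip(keys, keys[1:]):
            if a == b:
                raise DataError(f"duplicate record at w1={a[0]}, T={a[1]} K")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def T(self):
        import numpy as np

        return np.array([p.T for p in self.points])

    @property
    def x_exp(self):
        import numpy as np

        return np.array([p.x_exp for p in self.points])

    @property
    def label(self) -> str:
        return self.system.label


@dataclass(frozen=True)
class SoluteProperties:
    """Solid-state and structural constants of the solute.

    Parameters
    ----------
    Tm : melting temperature in K.
    dHfus : enthalpy of fusion in J/mol.
    M : molar mass in g/mol.
    hsp_groups : functional-group inventory for group-contribution methods.
    """

    name: str
    Tm: float
    dHfus: float
    M: float
    hsp_groups: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Tm <= 0 or self.dHfus <= 0 or self.M <= 0:
            raise DataError("Tm, dHfus and M must all be positive")


#: Dehydroabietic acid: onset melting point 443.22 K from DSC and fusion
#: enthalpy 17.19 kJ/mol (the DSC value; an alternative 19.17 kJ/mol appears
#: in quantum-chemistry workflows and can be passed explicitly instead).
DEHYDROABIETIC_ACID = SoluteProperties(
    name="dehydroabietic acid",
    Tm=443.22,
    dHfus=17190.0,
    M=300.442,
    hsp_groups={
        "CH3": 4,
        "CH2": 5,
        "CH": 2,
        "C": 2,
        "COOH": 1,
        "benzene ring": 1,
        "ring": 2,
    },
)


def mole_fraction_solubility(
    masses: Sequence[float], molar_masses: Sequence[float]
) -> float:
    """Mole fraction of component 1 from per-component masses.

    x1 = (m1/M1) / Σ(mi/Mi).  Supports a solute plus one or two solvents.
    """
    if len(masses) != len(molar_masses):
        raise DataError("masses and molar_masses must have equal length")
    if not 2 <= len(masses) <= 3:
        raise DataError("expected 2 or 3 components")
    if any(m < 0 for m in masses):
        raise DataError("masses must be non-negative")
    if any(M <= 0 for M in molar_masses):
        raise DataError("molar masses must be positive")
    moles = [m / M for m, M in zip(masses, molar_masses)]
    total = sum(moles)
    if total <= 0:
        raise DataError("at least one mass must be positive")
    return moles[0] / total


def solvent_mass_fraction(m1: float, m2: float) -> float:
    """Mass fraction w1 = m1/(m1+m2) of the first solvent in a binary mixture."""
    if m1 < 0 or m2 < 0:
        raise DataError("masses must be non-negative")
    if m1 + m2 <= 0:
        raise DataError("at least one mass must be positive")
    return m1 / (m1 + m2)


_CSV_HEADER = "system,w1,T_K,x_exp"


def save_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset to CSV with columns ``system, w1, T_K, x_exp``."""
    lines = [_CSV_HEADER]
    for p in dataset.points:
        w1 = p.w1 if p.w1 is not None else dataset.system.w1
        w1s = "" if w1 is None else repr(float(w1))
        lines.append(f"{dataset.system.label},{w1s},{p.T!r},{p.x_exp!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_dataset(
    path: str | Path,
    system: SolventSystem | None = None,
    pressure_kPa: float = 101.3,
) -> SolubilityDataset:
    """Read a dataset from CSV (columns ``system, w1, T_K, x_exp``).

    Row-level problems (non-numeric cells, out-of-range values) are reported
    with their 1-based line number.  If ``system`` is not given, a system is
    reconstructed from the file's ``system`` and ``w1`` columns.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    try:
        i_T, i_x = header.index("T_K"), header.index("x_exp")
    except ValueError as exc:
        raise DataError(f"{path}: missing required column: {exc}") from None
    i_w = header.index("w1") if "w1" in header else None
    i_sys = header.index("system") if "system" in header else None

    points: list[SolubilityPoint] = []
    sys_names: set[str] = set()
    w1_values: list[float | None] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) < len(header):
            raise DataError(f"{path}:{lineno}: expected {len(header)} cells")
        try:
            T = float(cells[i_T])
            x = float(cells[i_x])
            w1 = None
            if i_w is not None and cells[i_w]:
                w1 = float(cells[i_w])
        except ValueError:
            raise DataError(f"{path}:{lineno}: non-numeric cell") from None
        try:
            points.append(SolubilityPoint(T=T, x_exp=x, w1=w1))
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from None
        w1_values.append(w1)
        if i_sys is not None:
            sys_names.add(cells[i_sys])

    if system is None:
        name = sys_names.pop() if len(sys_names) == 1 else Path(path).stem
        uniq = {w for w in w1_values}
        if uniq == {None}:
            system = SolventSystem(names=(name,), w1=1.0)
            points = [replace(p, w1=None) for p in points]
        elif len(uniq) == 1:
            system = SolventSystem(names=(name,), w1=uniq.pop())
            points = [replace(p, w1=None) for p in points]
        else:
            system = SolventSystem(names=(name, ""), w1=None)
    elif system.w1 is not None:
        # composition is a system-level property; drop redundant per-point w1
        points = [replace(p, w1=None) for p in points]
    try:
        return SolubilityDataset(system=system, points=tuple(points), pressure_kPa=pressure_kPa)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


# --------------------------------------------------------------------------
# Built-in study data: measured mole-fraction solubility of dehydroabietic
# acid at P = 101.3 kPa (laser monitoring method; u(T)=0.1 K, u_r(x)=0.01).

_MONO = {
    "(-)-alpha-pinene": """
299.45 0.09417
303.55 0.10171
307.38 0.11025
311.40 0.11894
313.58 0.12536
318.00 0.13501
322.16 0.14751
325.37 0.15607
328.40 0.16499
330.70 0.17197
333.24 0.18171
337.83 0.19733
""",
    "p-cymene": """
300.60 0.17951
305.84 0.18870
308.85 0.19381
311.54 0.19877
314.24 0.20598
318.77 0.21406
321.54 0.22128
325.29 0.23048
328.20 0.23874
331.08 0.24592
334.75 0.25801
336.16 0.26287
""",
    "(-)-beta-caryophyllene": """
301.35 0.09789
304.60 0.10524
309.34 0.11578
313.25 0.12512
316.65 0.13314
319.75 0.14076
323.60 0.15004
325.96 0.15626
328.53 0.16307
331.53 0.17201
333.93 0.17997
336.86 0.18976
""",
}

# Equal-mass binary solvent mixtures (w1 = 0.5 of the first-named solvent).
_BINARY = {
    ("p-cymene", "(-)-beta-caryophyllene"): """
295.54 0.14409
298.90 0.15020
303.24 0.15784
308.34 0.16867
313.28 0.17961
318.45 0.18941
321.90 0.19954
325.75 0.21104
329.26 0.22113
332.24 0.22944
334.43 0.23727
337.75 0.24663
""",
    ("p-cymene", "(-)-alpha-pinene"): """
297.45 0.14197
301.84 0.15089
303.67 0.15530
309.45 0.16693
313.55 0.17713
318.15 0.18642
320.87 0.19347
324.46 0.20403
327.47 0.21218
330.85 0.22095
334.05 0.23113
338.75 0.24673
""",
    ("(-)-alpha-pinene", "(-)-beta-caryophyllene"): """
295.15 0.08338
300.45 0.09577
303.57 0.10417
307.25 0.11507
313.07 0.12970
315.99 0.13747
319.63 0.14686
323.93 0.15967
327.27 0.16973
331.14 0.18024
335.17 0.19484
339.46 0.20909
""",
}

# Composition scans: w1 of the first-named solvent varies along the rows.
_SCAN = {
    ("(-)-alpha-pinene", "p-cymene"): """
0.1 304.65 0.18572
0.2 309.45 0.18739
0.3 311.40 0.18672
0.4 313.45 0.18583
0.5 313.55 0.17713
0.6 314.25 0.17325
0.7 313.55 0.15997
0.8 314.95 0.15047
0.9 318.15 0.14841
""",
    ("p-cymene", "(-)-beta-caryophyllene"): """
0.1 323.50 0.16368
0.2 316.64 0.15576
0.3 317.95 0.17055
0.4 314.70 0.17427
0.5 313.28 0.17961
0.6 312.05 0.18090
0.7 311.20 0.18503
0.8 312.53 0.19505
0.9 313.30 0.20398
""",
    ("(-)-alpha-pinene", "(-)-beta-caryophyllene"): """
0.1 311.40 0.12665
0.2 312.40 0.12751
0.3 313.30 0.12837
0.4 315.55 0.13447
0.5 319.43 0.14686
0.6 319.75 0.14597
0.7 322.35 0.15191
0.8 324.05 0.15619
0.9 325.85 0.16078
""",
}


def _parse_block(block: str, with_w1: bool) -> tuple[SolubilityPoint, ...]:
    pts = []
    for ln in block.strip().splitlines():
        cells = ln.split()
        if with_w1:
            pts.append(SolubilityPoint(w1=float(cells[0]), T=float(cells[1]), x_exp=float(cells[2])))
        else:
            pts.append(SolubilityPoint(T=float(cells[0]), x_exp=float(cells[1])))
    return tuple(pts)


def builtin_fixtures() -> dict[str, SolubilityDataset]:
    """The study's nine measured datasets, keyed by solvent-system label.

    Three monosolvents and three equal-mass binaries (12 points each) plus
    three composition scans (9 points each); 99 records in total.
    """
    out: dict[str, SolubilityDataset] = {}
    for name, block in _MONO.items():
        sys = SolventSystem(names=(name,), w1=1.0, molar_masses=(MOLAR_MASSES[name],))
        out[sys.label] = SolubilityDataset(system=sys, points=_parse_block(block, False))
    for names, block in _BINARY.items():
        sys = SolventSystem(
            names=names, w1=0.5, molar_masses=tuple(MOLAR_MASSES[n] for n in names)
        )
        out[sys.label] = SolubilityDataset(system=sys, points=_parse_block(block, False))
    for names, block in _SCAN.items():
        sys = SolventSystem(
            names=names, w1=None, molar_masses=tuple(MOLAR_MASSES[n] for n in names)
        )
        out[sys.label] = SolubilityDataset(system=sys, points=_parse_block(block, True))
    return out
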