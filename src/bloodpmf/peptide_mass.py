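"""Monoisotopic mass calculus for peptides, ions, and fragment series.

All masses are in daltons (Da); mass-to-charge values in thomson (Th).
Computations are carried out at full floating-point precision; values are
only rounded for display (3 decimal places by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AminoAcidTable",
    "Peptide",
    "IonSpec",
    "STANDARD_TABLE",
    "PROTON_MASS",
    "WATER_MASS",
    "OXIDATION_MASS",
    "CO_MASS",
    "NH3_MASS",
    "neutral_mass",
    "mz",
    "ppm_error",
    "fragment_series",
    "nominal_mz",
]

#: Monoisotopic mass of a proton (Da).
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of water (Da).
WATER_MASS = 18.0105646863

#: Mass shift of methionine oxidation (Da).
OXIDATION_MASS = 15.9949146221

#: Carbon monoxide, the b -> a series offset (Da).
CO_MASS = 27.9949146221

#: Ammonia, the b -> c series offset (Da).
NH3_MASS = 17.0265491015

#: Monoisotopic residue masses of the 20 standard amino acids (Da).
_RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

_FRAGMENT_SERIES = ("a", "b", "c", "y")


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue mass table plus the constants needed for ion m/z arithmetic."""

    residue_masses: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MASSES))
    water: float = WATER_MASS
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residue_masses)
        if missing:
            raise ValueError(f"residue table missing standard residues: {sorted(missing)}")
        bad = [r for r, m in self.residue_masses.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for: {sorted(bad)}")

    def mass_of(self, residue: str, position: int | None = None) -> float:
        try:
            return self.residue_masses[residue]
        except KeyError:
            where = "" if position is None else f" at position {position}"
            raise ValueError(f"unknown residue code {residue!r}{where}") from None


#: Default table used throughout the package.
STANDARD_TABLE = AminoAcidTable()


@dataclass(frozen=True)
class Peptide:
    """An amino-acid sequence with an optional set of oxidised methionines.

    ``oxidized_positions`` holds 1-based indices into ``sequence``; every
    indexed residue must be a methionine.
    """

    sequence: str
    oxidized_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        object.__setattr__(self, "oxidized_positions", frozenset(self.oxidized_positions))
        n = len(self.sequence)
        for pos in self.oxidized_positions:
            if not 1 <= pos <= n:
                raise ValueError(f"oxidized position {pos} outside sequence of length {n}")
            if self.sequence[pos - 1] != "M":
                raise ValueError(
                    f"oxidized position {pos} is {self.sequence[pos - 1]!r}, not methionine"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IonSpec:
    """Charge state and adduct for converting neutral mass to m/z."""

    charge: int = 1
    adduct_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


def _position_masses(p: Peptide, t: AminoAcidTable) -> list[float]:
    """Per-position masses including the oxidation shift where applicable."""
    out = []
    for i, residue in enumerate(p.sequence, start=1):
        m = t.mass_of(residue, position=i)
        if i in p.oxidized_positions:
            m += OXIDATION_MASS
        out.append(m)
    return out


def neutral_mass(p: Peptide, t: AminoAcidTable = STANDARD_TABLE) -> float:
    """Monoisotopic neutral mass: residue sum + water + oxidation shifts."""
    return sum(_position_masses(p, t)) + t.water


def mz(p: Peptide, ion: IonSpec = IonSpec(), t: AminoAcidTable = STANDARD_TABLE) -> float:
    """m/z of the peptide under the given charge/adduct."""
    return (neutral_mass(p, t) + ion.charge * ion.adduct_mass) / ion.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def fragment_series(
    p: Peptide, series: str, t: AminoAcidTable = STANDARD_TABLE
) -> list[float]:
    """Singly protonated a/b/c (N-terminal) or y (C-terminal) fragment m/z.

    Returns ``len(p) - 1`` values ordered by fragment index (1..n-1).
    """
    if series not in _FRAGMENT_SERIES:
        raise ValueError(f"unknown fragment series {series!r}; expected one of {_FRAGMENT_SERIES}")
    if len(p) < 2:
        raise ValueError("fragment series require a peptide of length >= 2")
    masses = _position_masses(p, t)
    n = len(masses)
    if series == "y":
        suffix = 0.0
        out = []
        for i in range(1, n):
            suffix += masses[n - i]
            out.append(suffix + t.water + t.proton)
        return out
    prefix = 0.0
    out = []
    for i in range(1, n):
        prefix += masses[i - 1]
        b = prefix + t.proton
        if series == "b":
            out.append(b)
        elif series == "a":
            out.append(b - CO_MASS)
        else:  # c
            out.append(b + NH3_MASS)
    return out


def nominal_mz(x: float) -> int:
    """Nearest-integer nominal m/z label."""
    if x <= 0:
        raise ValueError(f"m/z must be positive, got {x}")
    return int(math.floor(x + 0.5))


def concat(p: Peptide, q: Peptide) -> Peptide:
    """Peptide bond condensation of two peptides (used by property tests)."""
    shifted = frozenset(i + len(p.sequence) for i in q.oxidized_positions)
    return Peptide(p.sequence + q.sequence, p.oxidized_positions | shifted)
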