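"""Exact-mass and elemental-formula arithmetic.

Everything downstream (transformation enumeration, extracted-ion screening,
fragment annotation, isotope-pattern inference) is ultimately arithmetic on
elemental compositions and their monoisotopic masses.  This module owns that
currency: a small immutable composition type over the CHNOClFS universe,
Hill-notation parsing/formatting, cation m/z with electron-mass correction,
ppm mass errors, ring-plus-double-bond equivalents, and coarse (unit-bin)
isotope patterns.

Monoisotopic masses are embedded as a fixed table (CODATA/IUPAC values) so
results do not drift with library versions.  The positive-mode convention is
[M+H]+ throughout: a cation's m/z is the summed atomic mass of its formula
minus one electron mass per positive charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementalComposition",
    "IonSpecies",
    "MassMeasurement",
    "FormulaError",
    "FormulaParseError",
    "NotASubformulaError",
    "parse_formula",
    "ion_mz",
    "ppm_error",
    "subtract",
    "rdbe",
    "isotope_pattern",
]

#: Supported element universe, in Hill order (C, H, then alphabetical).
ELEMENTS: tuple[str, ...] = ("C", "H", "Cl", "F", "N", "O", "S")

#: Monoisotopic atomic masses (u); carbon-12 is exact by definition.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "S": 31.97207117,
}

ELECTRON_MASS: float = 0.00054858

#: Isotope distributions as (mass-shift in unit bins, abundance) per element.
#: Shifts are relative to the monoisotopic isotope. F is monoisotopic.
ISOTOPE_ABUNDANCE: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "F": ((0, 1.0),),
    "Cl": ((0, 0.7577), (2, 0.2423)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}

#: Mass difference between 37Cl and 35Cl; used by generators emitting M+2 peaks.
CL37_CL35_SHIFT: float = 36.96590260 - 34.96885268


class FormulaError(ValueError):
    """Base class for formula-arithmetic failures."""


class FormulaParseError(FormulaError):
    """Malformed formula string; carries the offset of the bad token."""

    def __init__(self, text: str, offset: int, message: str):
        self.text = text
        self.offset = offset
        super().__init__(f"{message} at offset {offset} in {text!r}")


class NotASubformulaError(FormulaError):
    """Raised when a subtraction would produce a negative element count."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition(Mapping[str, int]):
    """Immutable non-negative integer element counts over CHNOClFS.

    Behaves as a mapping from element symbol to count (zero for absent
    elements).  Supports ``+`` and ``-`` (the latter raising
    :class:`NotASubformulaError` on any negative count) and subset testing
    via :meth:`contains`.
    """

    counts: tuple[int, ...] = field(default=(0,) * len(ELEMENTS))

    def __post_init__(self) -> None:
        if len(self.counts) != len(ELEMENTS):
            raise FormulaError("counts tuple must cover the element universe")
        if any(c < 0 for c in self.counts):
            raise FormulaError(f"negative element count in {self.counts}")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "ElementalComposition":
        unknown = set(d) - set(ELEMENTS)
        if unknown:
            raise FormulaError(f"unsupported element(s): {sorted(unknown)}")
        return cls(tuple(int(d.get(el, 0)) for el in ELEMENTS))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        try:
            return self.counts[ELEMENTS.index(element)]
        except ValueError:
            raise KeyError(element) from None

    def __iter__(self) -> Iterator[str]:
        return (el for el, c in zip(ELEMENTS, self.counts) if c)

    def __len__(self) -> int:
        return sum(1 for c in self.counts if c)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            tuple(a + b for a, b in zip(self.counts, other.counts))
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        diff = tuple(a - b for a, b in zip(self.counts, other.counts))
        if any(c < 0 for c in diff):
            raise NotASubformulaError(
                f"{other.hill()} is not a subformula of {self.hill()}"
            )
        return ElementalComposition(diff)

    def contains(self, other: "ElementalComposition") -> bool:
        """Element-wise ``other <= self``."""
        return all(a >= b for a, b in zip(self.counts, other.counts))

    @property
    def is_empty(self) -> bool:
        return not any(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass (u)."""
        return sum(c * MONOISOTOPIC_MASS[el] for el, c in zip(ELEMENTS, self.counts))

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H") + tuple(sorted(set(ELEMENTS) - {"C", "H"})):
            c = self[el]
            if c == 1:
                parts.append(el)
            elif c > 1:
                parts.append(f"{el}{c}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalComposition({self.hill() or 'empty'})"


EMPTY = ElementalComposition()


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-notation element-count string, e.g. ``"C21H24ClFNO2"``.

    Charge markers must be stripped by the caller.  Unknown element symbols
    and malformed tokens raise :class:`FormulaParseError` naming the offset.
    An empty string parses to the empty composition.
    """
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(text, pos, "malformed token")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in counts:
            # A one-letter prefix of a two-letter symbol typed in full caps
            # ("CL") would otherwise parse as C + L; report the real offset.
            raise FormulaParseError(text, pos, f"unknown element {symbol!r}")
        counts[symbol] += int(digits) if digits else 1
        pos = m.end()
    return ElementalComposition.from_dict(counts)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species: composition of the ion plus charge and parity.

    ``composition`` is the ion's own formula (for an [M+H]+ cation it already
    includes the extra proton's H).  ``radical`` marks an odd-electron
    (radical) cation; it does not change the m/z of a +1 ion but tracks
    electron parity through radical neutral losses such as Cl-dot.
    """

    composition: ElementalComposition
    charge: int = 1
    radical: bool = False

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise FormulaError("ion charge must be nonzero")

    @property
    def mz(self) -> float:
        return ion_mz(self)


@dataclass(frozen=True)
class MassMeasurement:
    """An observed m/z (Th), optionally with an intensity."""

    observed_mz: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.observed_mz <= 0:
            raise FormulaError("observed m/z must be positive")


def ion_mz(ion: IonSpecies) -> float:
    """m/z of an ion: (formula mass - charge x electron mass) / |charge|.

    The table-reporting convention in this package rounds to 4 decimals, but
    the value returned here is unrounded so mass additivity holds exactly.
    """
    if ion.composition.is_empty:
        raise FormulaError("cannot compute m/z of an empty composition")
    mass = ion.composition.monoisotopic_mass - ion.charge * ELECTRON_MASS
    return mass / abs(ion.charge)


def ppm_error(observed: MassMeasurement | float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise FormulaError("theoretical m/z must be positive")
    obs = observed.observed_mz if isinstance(observed, MassMeasurement) else observed
    return (obs - theoretical) / theoretical * 1e6


def subtract(
    minuend: ElementalComposition, subtrahend: ElementalComposition
) -> ElementalComposition:
    """Neutral-loss arithmetic: ``minuend - subtrahend``, error on negatives."""
    return minuend - subtrahend


def rdbe(composition: ElementalComposition) -> float:
    """Ring-plus-double-bond equivalents: C + 1 - (H+Cl+F)/2 + N/2.

    Oxygen and sulfur contribute zero.  Half-integer values are normal for
    even-electron cation formulas.
    """
    c = composition
    return c["C"] + 1 - (c["H"] + c["Cl"] + c["F"]) / 2 + c["N"] / 2


def isotope_pattern(
    ion: IonSpecies, n_isotopologues: int = 3
) -> list[tuple[int, float]]:
    """Coarse isotope pattern aggregated in unit mass-shift bins.

    Returns ``[(shift, relative_intensity), ...]`` for shifts
    ``0..n_isotopologues-1`` with the monoisotopic bin normalized to 1.0.
    Computed by the exact polynomial expansion of per-atom isotope
    distributions (convolution over unit bins); fine structure within a bin
    is deliberately not resolved.
    """
    max_shift = n_isotopologues - 1
    dist = [1.0] + [0.0] * max_shift
    for el, count in zip(ELEMENTS, ion.composition.counts):
        single = ISOTOPE_ABUNDANCE[el]
        for _ in range(count):
            new = [0.0] * (max_shift + 1)
            for shift, acc in enumerate(dist):
                if acc == 0.0:
                    continue
                for dshift, p in single:
                    if shift + dshift <= max_shift:
                        new[shift + dshift] += acc * p
            dist = new
    base = dist[0]
    if base == 0.0:
        raise FormulaError("degenerate isotope pattern (zero monoisotopic bin)")
    return [(shift, v / base) for shift, v in enumerate(dist)]


def format_mz(mz: float) -> float:
    """Round an m/z for reporting (4 decimals, round-half-even)."""
    return float(f"{mz:.4f}")


def format_ppm(ppm: float) -> float:
    """Round a ppm error for reporting (1 decimal, round-half-even)."""
    return float(f"{ppm:.1f}")
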