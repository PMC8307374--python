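"""Molecular-formula mass arithmetic for terpene-class confirmation.

GC-MS screening of terpene synthase products relies on the molecular ion:
a diterpene hydrocarbon (C20H32) gives a nominal [M]+ at m/z 272 and a
sesterterpene hydrocarbon (C25H40) at m/z 340, with the corresponding
alcohols at 290 and 358.  High-resolution spectra are matched against the
monoisotopic mass (e.g. C25H40 = 340.3130 Da).  Masses are computed under
the neutral-molecule convention — no electron-mass correction for [M]+ —
which is how such "calculated" values are conventionally printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Principal-isotope exact masses (Da), pinned so results are bit-stable.
MONOISOTOPIC_MASS = {
    "C": 12.0,  # exact by definition
    "H": 1.00782503,
    "O": 15.99491462,
    "N": 14.00307401,
    "S": 31.97207117,
}

#: Integer mass numbers of the principal isotopes.
NOMINAL_MASS = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32}

#: Molecular ions diagnostic for terpene classes (nominal m/z -> label).
TERPENE_ION_TABLE = {
    272: ("diterpene hydrocarbon", "C20H32"),
    290: ("diterpene alcohol", "C20H34O"),
    340: ("sesterterpene hydrocarbon", "C25H40"),
    358: ("sesterterpene alcohol", "C25H42O"),
}


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map, e.g. ``{"C": 25, "H": 40}``."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for elem, n in self.counts:
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {elem!r}")
            if n < 1:
                raise FormulaError(f"element {elem}: count must be >= 1")

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts)

    def combine(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return MolecularFormula(counts=tuple(merged.items()))


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula such as ``"C25H40"`` or ``"C20H34O"``.

    An element with no digit has count 1; zero counts, unknown elements,
    and stray characters are errors.
    """
    if not text:
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at offset {pos}")
        elem, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"element {elem}: zero count in {text!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return MolecularFormula(counts=tuple(counts.items()))


def monoisotopic_mass(formula: MolecularFormula | str, digits: int = 4) -> float:
    """Monoisotopic (principal-isotope) mass in Da, rounded to ``digits``
    decimals (4 by default, matching HR-MS reporting)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts)
    return round(total, digits)


def nominal_mass(formula: MolecularFormula | str) -> int:
    """Nominal (integer mass-number) mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(NOMINAL_MASS[e] * n for e, n in formula.counts)


def terpene_class_from_ion(mz: float, tolerance: float = 0.5) -> str | None:
    """Match an observed molecular ion to a terpene class.

    Returns the label of the nearest diagnostic ion within ``tolerance``
    m/z units, or None if nothing matches.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    best = None
    best_delta = None
    for ion, (label, _formula) in TERPENE_ION_TABLE.items():
        delta = abs(mz - ion)
        if delta <= tolerance and (best_delta is None or delta < best_delta):
            best, best_delta = label, delta
    return best
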