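"""Elemental formulas, monoisotopic masses, adduct m/z and ppm errors.

This is the arithmetic layer under every accurate-mass number in the
dereplication engine: Hill-notation formula parsing, exact monoisotopic
mass summation, singly charged positive-mode adduct m/z (with the
electron mass subtracted), and the signed ppm mass-error convention used
to compare theoretical with experimental m/z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "ElementalFormula",
    "IonSpecies",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ION_SPECIES",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
]

#: Monoisotopic atomic masses in Da (IUPAC/CODATA; carbon-12 exact).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
}

#: Electron rest mass in Da; subtracted once per positive charge.
ELECTRON_MASS = 0.00054858

#: Mass of a proton (H minus one electron) in Da.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid compositions."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: a map from element symbol to count.

    Counts are nonnegative integers and every element must have an entry
    in :data:`MONOISOTOPIC_MASS`. The canonical string form uses Hill
    order (C first, then H, then the rest alphabetically) and round-trips
    through :func:`parse_formula`.
    """

    counts: Tuple[Tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        seen: Dict[str, int] = {}
        for symbol, n in self.counts:
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {symbol} must be a nonnegative integer, got {n!r}")
            seen[symbol] = seen.get(symbol, 0) + n
        canonical = tuple(sorted(((s, n) for s, n in seen.items() if n > 0), key=_hill_key))
        object.__setattr__(self, "counts", canonical)

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(counts.items()))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, symbol: str) -> int:
        return dict(self.counts).get(symbol, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for s, n in other.counts:
            merged[s] = merged.get(s, 0) + n
        return ElementalFormula.from_dict(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for s, n in other.counts:
            merged[s] = merged.get(s, 0) - n
            if merged[s] < 0:
                raise FormulaError(
                    f"cannot remove {n} {s} from {self}: only {self[s]} available"
                )
        return ElementalFormula.from_dict(merged)

    def contains(self, other: "ElementalFormula") -> bool:
        return all(self[s] >= n for s, n in other.counts)

    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:
        return "".join(f"{s}{n if n != 1 else ''}" for s, n in self.counts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({str(self)!r})"

    def __bool__(self) -> bool:
        return bool(self.counts)


def _hill_key(item: Tuple[str, int]) -> Tuple[int, str]:
    symbol = item[0]
    order = {"C": 0, "H": 1}
    return (order.get(symbol, 2), symbol)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C45H76O19"``.

    Repeated element symbols are summed. Raises :class:`FormulaError`
    on empty input, unknown symbols, or explicit zero counts.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero or negative count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return ElementalFormula.from_dict(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Exact monoisotopic mass of a neutral composition, in Da."""
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in f.counts)


# --- ion species ------------------------------------------------------------

_EMPTY = ElementalFormula()
_H = ElementalFormula.from_dict({"H": 1})
_H2O = ElementalFormula.from_dict({"H": 2, "O": 1})
_NA = ElementalFormula.from_dict({"Na": 1})


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged positive adduct of a neutral molecule M.

    ``label`` uniquely determines the atoms added to / removed from M;
    the m/z is (neutral mass + added − removed − one electron) / charge.
    """

    label: str
    atoms_added: ElementalFormula
    atoms_removed: ElementalFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged positive ions are in scope")


#: The in-scope positive-mode precursor species.
ION_SPECIES: Dict[str, IonSpecies] = {
    "[M+Na]+": IonSpecies("[M+Na]+", _NA, _EMPTY),
    "[M+H]+": IonSpecies("[M+H]+", _H, _EMPTY),
    "[M+H-H2O]+": IonSpecies("[M+H-H2O]+", _H, _H2O),
    "[M+H-2xH2O]+": IonSpecies(
        "[M+H-2xH2O]+", _H, ElementalFormula.from_dict({"H": 4, "O": 2})
    ),
}

# Unicode minus / multiplication sign and surrounding spaces are accepted
# on input; the canonical labels above are plain ASCII.
_LABEL_TRANSLATION = str.maketrans({"−": "-", "–": "-", "×": "x"})


def normalize_ion_label(label: str) -> str:
    return label.translate(_LABEL_TRANSLATION).replace(" ", "")


def get_ion_species(label: str) -> IonSpecies:
    key = normalize_ion_label(label)
    try:
        return ION_SPECIES[key]
    except KeyError:
        raise KeyError(f"unknown ion species label: {label!r}") from None


def ion_mz(f: ElementalFormula, ion: IonSpecies | str) -> float:
    """Theoretical m/z of an adduct ion of the neutral composition ``f``.

    Full precision is kept internally; display rounds to 4 decimals.
    Raises :class:`FormulaError` if the removal exceeds available atoms.
    """
    if isinstance(ion, str):
        ion = get_ion_species(ion)
    if not (f + ion.atoms_added).contains(ion.atoms_removed):
        raise FormulaError(
            f"ion {ion.label} removes atoms not present in {f} plus adduct"
        )
    m = (
        monoisotopic_mass(f)
        + monoisotopic_mass(ion.atoms_added)
        - monoisotopic_mass(ion.atoms_removed)
        - ELECTRON_MASS * ion.charge
    )
    return m / ion.charge


def ppm_error(theoretical: float, experimental: float) -> float:
    """Signed mass error, (theoretical − experimental)/theoretical × 1e6.

    This sign convention reproduces every printed error in the reference
    annotation table. Both arguments must be positive.
    """
    if theoretical <= 0 or experimental <= 0:
        raise ValueError("m/z values must be positive")
    return (theoretical - experimental) / theoretical * 1e6


def mz_display(mz: float) -> float:
    """m/z rounded to the 4 decimal places used in report tables."""
    return round(mz, 4)


def ppm_display(ppm: float) -> float:
    """ppm error rounded to 1 decimal place for display."""
    return round(ppm, 1)


def formula_union(formulas: Iterable[ElementalFormula]) -> ElementalFormula:
    total = ElementalFormula()
    for f in formulas:
        total = total + f
    return total
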