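"""Compositional models of steroidal saponin candidates.

A candidate is described by what positive-mode ESI-QTOF MS/MS can see:
the aglycone skeleton class (furostanol with a C22 hydroxyl, which
dehydrates in-source, versus spirostanol-type), the number of glycosidic
hexose units (glucose vs. galactose is isobaric and kept only as a
label), an optional extra aglycone hydroxyl, Δ25(27) unsaturation, and
the C25 epimer configuration used for retention-time disambiguation.

Three additional *pathway annotations* record how a candidate's observed
fragmentation deviates from the default cascade — when the 22-OH water
loss happens relative to the sugar ladder, whether the ladder root ion
itself is reported, and an override of the E-ring cleavage composition.
They exist because isobaric candidates in the reference set fragment
along distinguishable routes that composition alone cannot predict.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence

from .chem import ElementalFormula, FormulaError, parse_formula

__all__ = [
    "SaponinCandidate",
    "CandidateSet",
    "molecular_formula",
    "load_library",
    "builtin_library",
]

HEXOSE_RESIDUE = parse_formula("C6H10O5")

_SKELETONS = {"furostanol", "spirostanol"}
_DEHYDRATION = {"early", "late", "none"}
_C25 = {"R", "S", "unspecified"}


@dataclass(frozen=True)
class SaponinCandidate:
    """One steroidal saponin hypothesis in the dereplication library."""

    name: str
    skeleton: str  # "furostanol" | "spirostanol"
    c22_hydroxyl: bool
    extra_aglycone_oh: int  # 0 or 1
    ene_25_27: bool
    n_hexose: int
    c25_config: str  # "R" | "S" | "unspecified"
    aglycone_formula: ElementalFormula
    sugar_labels: Sequence[str] = ()
    is_standard: bool = False
    # pathway annotations (see module docstring)
    dehydration: str = "early"  # "early" | "late" | "none"
    root_listed: bool = True
    ering_loss: Optional[str] = None  # formula string override, None = derive
    extra_h2o_branch: bool = False
    rt_ref: Optional[float] = None  # reference retention time, minutes

    def __post_init__(self) -> None:
        if self.skeleton not in _SKELETONS:
            raise ValueError(f"unknown skeleton {self.skeleton!r}")
        if self.c22_hydroxyl and self.skeleton != "furostanol":
            raise ValueError("a C22 hydroxyl implies a furostanol skeleton")
        if self.extra_aglycone_oh not in (0, 1):
            raise ValueError("extra_aglycone_oh must be 0 or 1")
        if self.n_hexose < 0:
            raise ValueError("n_hexose must be nonnegative")
        if self.c25_config not in _C25:
            raise ValueError(f"c25_config must be one of {_C25}")
        if self.dehydration not in _DEHYDRATION:
            raise ValueError(f"dehydration must be one of {_DEHYDRATION}")
        if self.skeleton == "spirostanol" and self.dehydration != "none":
            raise ValueError("spirostanol candidates have no 22-OH water loss")

    @property
    def formula(self) -> ElementalFormula:
        return molecular_formula(self)

    def with_config(self, c25_config: str) -> "SaponinCandidate":
        return replace(self, c25_config=c25_config)


def molecular_formula(c: SaponinCandidate) -> ElementalFormula:
    """Neutral molecular formula: aglycone plus dehydrated hexose residues.

    Each glycosidic hexose contributes C6H10O5 (162.0528 Da), the mass
    the sugar ladder sheds per cleaved bond.
    """
    f = c.aglycone_formula
    for _ in range(c.n_hexose):
        f = f + HEXOSE_RESIDUE
    return f


class CandidateSet:
    """An ordered saponin library with isomer lookup by molecular formula.

    Library order is elution order on the reference C18 gradient; the
    retention-time disambiguation step relies on it when several
    isobaric candidates fit one spectrum.
    """

    def __init__(self, candidates: Sequence[SaponinCandidate]):
        names = [c.name for c in candidates]
        if len(set(names)) != len(names):
            raise ValueError("candidate names must be unique")
        self._candidates: List[SaponinCandidate] = list(candidates)
        self._by_name: Dict[str, SaponinCandidate] = {c.name: c for c in candidates}
        self._by_formula: Dict[str, List[SaponinCandidate]] = {}
        for c in candidates:
            self._by_formula.setdefault(str(c.formula), []).append(c)

    def __iter__(self) -> Iterator[SaponinCandidate]:
        return iter(self._candidates)

    def __len__(self) -> int:
        return len(self._candidates)

    def __getitem__(self, name: str) -> SaponinCandidate:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def standards(self) -> List[SaponinCandidate]:
        return [c for c in self._candidates if c.is_standard]

    def isomer_group(self, f: ElementalFormula | str) -> List[SaponinCandidate]:
        """All candidates whose molecular formula equals ``f``, in library order."""
        key = str(f if isinstance(f, ElementalFormula) else parse_formula(f))
        return list(self._by_formula.get(key, []))


# --- serialization ----------------------------------------------------------

_COLUMNS = [
    "name",
    "is_standard",
    "skeleton",
    "c22_hydroxyl",
    "extra_aglycone_oh",
    "ene_25_27",
    "n_hexose",
    "c25_config",
    "aglycone_formula",
    "sugar_labels",
    "dehydration",
    "root_listed",
    "ering_loss",
    "extra_h2o_branch",
    "rt_ref",
]


def _parse_bool(s: str) -> bool:
    return s.strip() in {"1", "true", "True", "yes"}


def load_library(path: str | Path) -> CandidateSet:
    """Read a tab-separated candidate library file."""
    path = Path(path)
    candidates = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(_strip_comments(fh), delimiter="\t")]
    if rows and any(col not in rows[0] for col in _COLUMNS):
        missing = [c for c in _COLUMNS if c not in rows[0]]
        raise ValueError(f"library file {path} missing columns: {missing}")
    for i, row in enumerate(rows, start=2):
        try:
            candidates.append(
                SaponinCandidate(
                    name=row["name"],
                    skeleton=row["skeleton"],
                    c22_hydroxyl=_parse_bool(row["c22_hydroxyl"]),
                    extra_aglycone_oh=int(row["extra_aglycone_oh"]),
                    ene_25_27=_parse_bool(row["ene_25_27"]),
                    n_hexose=int(row["n_hexose"]),
                    c25_config=row["c25_config"],
                    aglycone_formula=parse_formula(row["aglycone_formula"]),
                    sugar_labels=tuple(
                        s for s in row["sugar_labels"].split(",") if s
                    ),
                    is_standard=_parse_bool(row["is_standard"]),
                    dehydration=row["dehydration"],
                    root_listed=_parse_bool(row["root_listed"]),
                    ering_loss=row["ering_loss"] or None
                    if row["ering_loss"] != "auto"
                    else None,
                    extra_h2o_branch=_parse_bool(row["extra_h2o_branch"]),
                    rt_ref=float(row["rt_ref"]) if row["rt_ref"] else None,
                )
            )
        except (KeyError, ValueError, FormulaError) as exc:
            raise ValueError(f"{path}:{i}: bad library row: {exc}") from exc
    return CandidateSet(candidates)


def save_library(cs: CandidateSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for c in cs:
            writer.writerow(
                [
                    c.name,
                    int(c.is_standard),
                    c.skeleton,
                    int(c.c22_hydroxyl),
                    c.extra_aglycone_oh,
                    int(c.ene_25_27),
                    c.n_hexose,
                    c.c25_config,
                    str(c.aglycone_formula),
                    ",".join(c.sugar_labels),
                    c.dehydration,
                    int(c.root_listed),
                    c.ering_loss or "auto",
                    int(c.extra_h2o_branch),
                    "" if c.rt_ref is None else c.rt_ref,
                ]
            )


def _strip_comments(lines: Iterator[str] | Sequence[str]) -> Iterator[str]:
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line


def builtin_library() -> CandidateSet:
    """The packaged reference library of the fifteen identified saponins.

    Six entries (timosaponins BII, BIII, G, AIII, AIV and *Anemarrhena*
    saponin I) are flagged as authentic standards.
    """
    with resources.as_file(
        resources.files("saposcreen.data") / "library.tsv"
    ) as p:
        return load_library(p)
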