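"""Predicted ESI-MS/MS fragmentation trees for saponin glycosides.

Positive-mode QTOF spectra of steroidal saponins follow a small grammar
of neutral losses: in-source dehydration of the labile C22 hydroxyl
(furostanols), a ladder of glycosidic hexose losses (162.0528 Da each),
cleavage of the aglycone E-ring (C8H16O2 when the side chain is
saturated, C8H14O2 with Δ25(27) unsaturation), and final water losses.
``predict_fragments`` expands that grammar for one candidate into a tree
of labelled ions; ``match_fragments`` scores an observed peak list
against the tree's protonated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .chem import (
    ElementalFormula,
    FormulaError,
    get_ion_species,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)
from .library import SaponinCandidate

__all__ = [
    "NEUTRAL_LOSSES",
    "FragmentIon",
    "FragmentationTree",
    "Tolerance",
    "FragmentMatch",
    "MatchResult",
    "predict_fragments",
    "match_fragments",
]

#: In-scope neutral losses (formula string -> composition).
NEUTRAL_LOSSES = {
    "H2O": parse_formula("H2O"),
    "C6H10O5": parse_formula("C6H10O5"),  # dehydrated hexose residue
    "C8H16O2": parse_formula("C8H16O2"),  # E-ring, saturated side chain
    "C8H14O2": parse_formula("C8H14O2"),  # E-ring, Delta-25(27) unsaturated
    "C8H18O2": parse_formula("C8H18O2"),  # E-ring, hydroxylated side chain
}

_H = parse_formula("H")
_H2O = NEUTRAL_LOSSES["H2O"]
_HEXOSE = NEUTRAL_LOSSES["C6H10O5"]


@dataclass(frozen=True)
class FragmentIon:
    """One predicted ion: a loss-path label, composition and m/z.

    ``step`` is the generation depth (0 = precursor adducts);
    ``in_series`` marks membership of the reported protonated fragment
    series (the integer ladder printed in annotation tables).
    ``parent`` and ``loss`` record the tree edge that produced the ion.
    """

    label: str
    formula: ElementalFormula
    mz: float
    step: int
    in_series: bool = True
    parent: Optional[str] = None
    loss: Optional[str] = None


@dataclass(frozen=True)
class FragmentationTree:
    candidate: str
    ions: Tuple[FragmentIon, ...]

    @property
    def precursor_adducts(self) -> List[FragmentIon]:
        return [i for i in self.ions if i.step == 0]

    @property
    def protonated_series(self) -> List[FragmentIon]:
        """The reported fragment ions, in ladder order."""
        return [i for i in self.ions if i.in_series]

    def nominal_ladder(self) -> List[int]:
        """Integer-rounded m/z of the protonated series, as tables print it."""
        return [round(i.mz) for i in self.protonated_series]

    def ion(self, label: str) -> FragmentIon:
        for i in self.ions:
            if i.label == label:
                return i
        raise KeyError(label)


def _protonated(f: ElementalFormula) -> ElementalFormula:
    """Composition of the protonated (charge-carrying) ion of neutral f."""
    return f + _H


def predict_fragments(c: SaponinCandidate) -> FragmentationTree:
    """Expand the fragmentation grammar for one candidate.

    The tree holds the precursor adducts ([M+Na]+ always, plus
    [M+H-H2O]+ for C22-hydroxylated furostanols or [M+H]+ otherwise)
    and the protonated fragment series: the hexose ladder, the E-ring
    cleavage product and its water loss, with the candidate's pathway
    annotations deciding where the 22-OH dehydration sits and which
    E-ring composition leaves.
    """
    M = c.formula
    ions: List[FragmentIon] = []

    # step 0: the sodiated precursor (always observed)
    ions.append(
        FragmentIon(
            "[M+Na]+", M + parse_formula("Na"), ion_mz(M, "[M+Na]+"), 0, in_series=False
        )
    )

    mh_formula = _protonated(M)
    mh_mz = ion_mz(M, "[M+H]+")

    series: List[FragmentIon] = []

    def push(parts: List[str], formula: ElementalFormula, mz: float, step: int,
             parent: Optional[str], loss: Optional[str], listed: bool = True) -> FragmentIon:
        label = "[M+H" + "".join(parts) + "]+" if parts else "[M+H]+"
        ion = FragmentIon(label, formula, mz, step, in_series=listed,
                          parent=parent, loss=loss)
        series.append(ion)
        return ion

    h2o_mass = monoisotopic_mass(_H2O)
    hex_mass = monoisotopic_mass(_HEXOSE)

    if c.skeleton == "furostanol" and c.c22_hydroxyl and c.dehydration == "early":
        # ladder root is the in-source dehydrated ion [M+H-H2O]+
        mh = push([], mh_formula, mh_mz, 1, None, None, listed=False)
        root = push(["-H2O"], mh_formula - _H2O, mh_mz - h2o_mass, 2,
                    mh.label, "H2O")
        root_parts = ["-H2O"]
        ladder_parent = root
    elif c.skeleton == "furostanol" and c.c22_hydroxyl:
        # "late" dehydration: the dehydrated precursor is observed, but
        # the sugar ladder keeps the 22-OH and runs from [M+H]+ itself
        mh = push([], mh_formula, mh_mz, 1, None, None, listed=False)
        push(["-H2O"], mh_formula - _H2O, mh_mz - h2o_mass, 2, mh.label, "H2O")
        ladder_parent = mh
        root_parts = []
    else:
        # spirostanol: the protonated molecule is the series root; a few
        # compounds report it among the fragments, most do not
        ladder_parent = push([], mh_formula, mh_mz, 1, None, None,
                             listed=c.root_listed)
        root_parts = []

    # hexose ladder
    parts = list(root_parts)
    node = ladder_parent
    for k in range(1, c.n_hexose + 1):
        parts = list(root_parts) + ([f"-{k}x162"] if k > 1 else ["-162"])
        node = push(
            parts,
            node.formula - _HEXOSE,
            node.mz - hex_mass,
            node.step + 1,
            node.label,
            "C6H10O5",
        )
    deglyc = node
    deglyc_parts = parts

    # post-ladder chemistry on the bare aglycone ion
    if c.extra_h2o_branch:
        # a separate dehydration branch is reported, but the E-ring
        # cleavage proceeds from the intact deglycosylated ion
        push(
            deglyc_parts + ["-H2O"],
            deglyc.formula - _H2O,
            deglyc.mz - h2o_mass,
            deglyc.step + 1,
            deglyc.label,
            "H2O",
        )
        ering_parent, ering_parts = deglyc, deglyc_parts
    elif c.extra_aglycone_oh or c.dehydration == "late":
        # a hydroxyl (extra aglycone OH, or the retained 22-OH) is still
        # present and leaves before the E-ring cleavage
        x = push(
            deglyc_parts + ["-H2O"],
            deglyc.formula - _H2O,
            deglyc.mz - h2o_mass,
            deglyc.step + 1,
            deglyc.label,
            "H2O",
        )
        ering_parent, ering_parts = x, deglyc_parts + ["-H2O"]
    else:
        ering_parent, ering_parts = deglyc, deglyc_parts

    loss_name = c.ering_loss or ("C8H14O2" if c.ene_25_27 else "C8H16O2")
    if loss_name not in NEUTRAL_LOSSES:
        raise FormulaError(f"unknown E-ring loss {loss_name!r} for {c.name}")
    ering_loss = NEUTRAL_LOSSES[loss_name]
    e1 = push(
        ering_parts + [f"-{loss_name}"],
        ering_parent.formula - ering_loss,
        ering_parent.mz - monoisotopic_mass(ering_loss),
        ering_parent.step + 1,
        ering_parent.label,
        loss_name,
    )
    push(
        ering_parts + [f"-{loss_name}", "-H2O"],
        e1.formula - _H2O,
        e1.mz - h2o_mass,
        e1.step + 1,
        e1.label,
        "H2O",
    )

    return FragmentationTree(c.name, tuple(ions) + tuple(series))


# --- matching ---------------------------------------------------------------


@dataclass(frozen=True)
class Tolerance:
    """A matching window: absolute (Da) or relative (ppm)."""

    da: Optional[float] = None
    ppm: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.da is None) == (self.ppm is None):
            raise ValueError("specify exactly one of da= or ppm=")
        value = self.da if self.da is not None else self.ppm
        if value <= 0:
            raise ValueError("tolerance must be positive")

    def window(self, mz: float) -> float:
        if self.da is not None:
            return self.da
        return mz * self.ppm * 1e-6


@dataclass(frozen=True)
class FragmentMatch:
    label: str
    predicted_mz: float
    observed_mz: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.predicted_mz


@dataclass(frozen=True)
class MatchResult:
    matches: Tuple[FragmentMatch, ...]
    n_predicted: int

    @property
    def coverage(self) -> float:
        return len(self.matches) / self.n_predicted

    @property
    def matched_labels(self) -> List[str]:
        return [m.label for m in self.matches]


def match_fragments(
    tree: FragmentationTree,
    observed: Sequence[float],
    tol: Tolerance,
) -> MatchResult:
    """Greedily match observed fragment m/z against the predicted series.

    Each predicted ion (ladder order) takes the nearest unused observed
    peak within the window; each observed peak is used at most once.
    Coverage is matched / predicted over the protonated series.
    """
    predicted = tree.protonated_series
    if not predicted:
        raise ValueError(f"candidate {tree.candidate!r} predicts no fragments")
    used = [False] * len(observed)
    matches: List[FragmentMatch] = []
    for ion in predicted:
        best_j, best_d = -1, float("inf")
        w = tol.window(ion.mz)
        for j, obs in enumerate(observed):
            if used[j]:
                continue
            d = abs(obs - ion.mz)
            if d <= w and d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            used[best_j] = True
            matches.append(FragmentMatch(ion.label, ion.mz, observed[best_j]))
    return MatchResult(tuple(matches), len(predicted))
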