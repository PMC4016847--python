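"""Rule-based dereplication cascade for saponin QTOF spectra.

A spectrum is annotated by (1) matching its precursor m/z against the
library's theoretical adduct masses within a ppm tolerance, (2)
requiring the candidate's full predicted fragment ladder in the observed
peak list, (3) checking that the diagnostic skeleton / hydroxylation
calls drawn from the spectrum do not contradict the candidate, and (4)
resolving isobaric C25 epimers by elution order (the 25R epimer elutes
later than 25S on reversed phase). Identifications are confirmed when
the candidate was run as an authentic standard, otherwise tentative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    ElementalFormula,
    get_ion_species,
    ion_mz,
    mz_display,
    normalize_ion_label,
    ppm_error,
)
from .fragmentation import (
    FragmentationTree,
    MatchResult,
    Tolerance,
    match_fragments,
    predict_fragments,
)
from .library import CandidateSet, SaponinCandidate

__all__ = [
    "Spectrum",
    "AnnotationRecord",
    "AnnotationConfig",
    "classify_skeleton",
    "count_hexose_losses",
    "aglycone_hydroxylation_state",
    "assign_c25_configuration",
    "annotate",
    "HEXOSE_MASS",
]

HEXOSE_MASS = 162.0528234295

FUROSTANOL_C22_OH = "furostanol+C22-OH"
SPIROSTANOL_TYPE = "spirostanol-type"
UNDETERMINED = "undetermined"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Spectrum:
    """An observed precursor with its fragment peak list."""

    peak_id: str
    rt_min: float
    precursor_mz: float
    precursor_ions_seen: Tuple[str, ...]
    fragments: Tuple[float, ...]
    intensities: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be nonnegative")
        if self.precursor_mz <= 0 or any(f <= 0 for f in self.fragments):
            raise ValueError("all m/z values must be positive")
        if self.intensities is not None and len(self.intensities) != len(self.fragments):
            raise ValueError("intensities must parallel fragments")
        object.__setattr__(
            self,
            "precursor_ions_seen",
            tuple(normalize_ion_label(s) for s in self.precursor_ions_seen),
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated peak: the dereplication table row for a spectrum."""

    peak_id: str
    rt_min: float
    assigned_formula: Optional[ElementalFormula]
    selected_ion: str
    theoretical_mz: Optional[float]
    experimental_mz: float
    error_ppm: Optional[float]
    matched_fragment_labels: Tuple[str, ...]
    skeleton_call: str
    n_hexose_call: int
    extra_oh_call: Optional[int]
    ene_call: Optional[bool]
    identification: str
    confidence: str  # "standard-confirmed" | "tentative" | "class-only"
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationConfig:
    """Matching tolerances and conventions for the cascade."""

    precursor_ppm_tol: float = 5.0
    fragment_tol: Tolerance = field(default_factory=lambda: Tolerance(da=0.5))
    precursor_ion: str = "[M+Na]+"
    require_full_ladder: bool = True


# --- diagnostic rules -------------------------------------------------------


def classify_skeleton(s: Spectrum) -> str:
    """Skeleton class from which precursor adducts were observed.

    C22-hydroxylated furostanols dehydrate in-source, so they show
    [M+Na]+ and [M+H-H2O]+ but no [M+H]+; a detected [M+H]+ marks a
    spirostanol-type saponin. Anything else is undetermined.
    """
    if not s.precursor_ions_seen:
        raise ValueError("precursor_ions_seen must be non-empty")
    seen = set(s.precursor_ions_seen)
    if "[M+H]+" in seen:
        return SPIROSTANOL_TYPE
    if "[M+Na]+" in seen and "[M+H-H2O]+" in seen:
        return FUROSTANOL_C22_OH
    return UNDETERMINED


def count_hexose_losses(
    fragments: Sequence[float], root_mz: float, tol: Tolerance
) -> int:
    """Length of the longest consecutive hexose-loss chain below a root.

    Counts k = 1, 2, ... while root − k×162.0528 is present in the
    fragment list within tolerance; the root itself need not be present.
    Targets are exact multiples below the root, so one noisy rung does
    not shift the windows further down the ladder.
    """
    k = 0
    while True:
        target = root_mz - (k + 1) * HEXOSE_MASS
        if target <= 0:
            break
        w = tol.window(target)
        if not any(abs(f - target) <= w for f in fragments):
            break
        k += 1
    return k


def _present(fragments: Sequence[float], nominal: float, tol: Tolerance) -> bool:
    w = tol.window(nominal)
    return any(abs(f - nominal) <= w for f in fragments)


def aglycone_hydroxylation_state(
    fragments: Sequence[float], tol: Tolerance
) -> Optional[int]:
    """Diagnose the extra aglycone hydroxyl from the low-mass ion series.

    The unsubstituted aglycone yields the 417/273/255 triple; one extra
    hydroxyl shifts the series to 433/415 (with 271/253 supporting).
    Returns 0 or 1, ``None`` when neither series is complete, and raises
    when both series are present (a contradictory spectrum).
    """
    bare = all(_present(fragments, m, tol) for m in (417, 273, 255))
    hydroxylated = all(_present(fragments, m, tol) for m in (433, 415))
    if bare and hydroxylated:
        raise ValueError("both the 417/273/255 and 433/415 series are present")
    if bare:
        return 0
    if hydroxylated:
        return 1
    return None


def assign_c25_configuration(
    group: List[AnnotationRecord], candidates: Sequence[SaponinCandidate]
) -> List[AnnotationRecord]:
    """Resolve C25 epimers within one isobaric record group by elution order.

    Records (sorted by retention time) are assigned the group's
    candidates in library order; wherever two assigned candidates form a
    25R/25S pair of the same parent structure, the later-eluting record
    must carry the 25R variant, swapping the pair if needed. Records
    beyond the number of candidates are flagged unresolved.
    """
    records = sorted(group, key=lambda r: r.rt_min)
    assigned: List[AnnotationRecord] = []
    names = [c.name for c in candidates]
    for i, rec in enumerate(records):
        if i < len(names):
            assigned.append(replace(rec, identification=names[i]))
        else:
            assigned.append(
                replace(rec, identification="unassigned",
                        confidence="class-only",
                        flags=rec.flags + ("unresolved-isomer",))
            )
    # enforce the 25R-later rule on epimer pairs
    by_index = {c.name: c for c in candidates}
    for i in range(len(assigned)):
        for j in range(i + 1, len(assigned)):
            a, b = assigned[i], assigned[j]
            ca, cb = by_index.get(a.identification), by_index.get(b.identification)
            if ca is None or cb is None:
                continue
            if _is_epimer_pair(ca, cb) and ca.c25_config == "R" and cb.c25_config == "S":
                # earlier record holds the R epimer: swap
                assigned[i] = replace(a, identification=cb.name)
                assigned[j] = replace(b, identification=ca.name)
    return assigned


def _is_epimer_pair(a: SaponinCandidate, b: SaponinCandidate) -> bool:
    base = lambda n: n.removeprefix("25R-").removeprefix("25S-")
    return (
        {a.c25_config, b.c25_config} == {"R", "S"}
        and base(a.name).lower() == base(b.name).lower()
    )


# --- the cascade ------------------------------------------------------------


def _candidate_calls(tree: FragmentationTree) -> Optional[int]:
    """Expected hydroxylation-series call implied by a predicted ladder."""
    nominal = set(tree.nominal_ladder())
    if {433, 415} <= nominal:
        return 1
    if {417, 273, 255} <= nominal:
        return 0
    return None


def _consistent(
    s: Spectrum,
    c: SaponinCandidate,
    tree: FragmentationTree,
    cfg: AnnotationConfig,
    flags: List[str],
) -> bool:
    skeleton = classify_skeleton(s)
    if skeleton == FUROSTANOL_C22_OH and not (
        c.skeleton == "furostanol" and c.c22_hydroxyl
    ):
        return False
    if skeleton == SPIROSTANOL_TYPE and c.skeleton != "spirostanol":
        return False

    # the hexose chain hangs off the dehydrated ion for early-dehydrating
    # furostanols and off the protonated molecule otherwise (whether or
    # not that root ion is itself reported among the fragments)
    if c.skeleton == "furostanol" and c.c22_hydroxyl and c.dehydration == "early":
        ladder_root_mz = tree.ion("[M+H-H2O]+").mz
    else:
        ladder_root_mz = tree.ion("[M+H]+").mz
    # lower-bound check: the terminal E-ring + H2O product sits 162.13 Da
    # below the bare aglycone ion, indistinguishable from one more hexose
    # loss at unit precision, so the observed chain may exceed n_hexose
    n_hex = count_hexose_losses(s.fragments, ladder_root_mz, cfg.fragment_tol)
    if n_hex < c.n_hexose:
        return False

    try:
        state = aglycone_hydroxylation_state(s.fragments, cfg.fragment_tol)
    except ValueError:
        flags.append("ambiguous-hydroxylation-series")
        return False
    expected = _candidate_calls(tree)
    if state is not None and expected is not None and state != expected:
        return False
    return True


def _class_only_record(s: Spectrum, cfg: AnnotationConfig) -> AnnotationRecord:
    try:
        state = aglycone_hydroxylation_state(s.fragments, cfg.fragment_tol)
        flags: Tuple[str, ...] = ()
    except ValueError:
        state, flags = None, ("ambiguous-hydroxylation-series",)
    return AnnotationRecord(
        peak_id=s.peak_id,
        rt_min=s.rt_min,
        assigned_formula=None,
        selected_ion=cfg.precursor_ion,
        theoretical_mz=None,
        experimental_mz=s.precursor_mz,
        error_ppm=None,
        matched_fragment_labels=(),
        skeleton_call=classify_skeleton(s),
        n_hexose_call=count_hexose_losses(
            s.fragments, s.precursor_mz, cfg.fragment_tol
        ),
        extra_oh_call=state,
        ene_call=None,
        identification="unassigned",
        confidence="class-only",
        flags=flags,
    )


def annotate(
    spectra: Sequence[Spectrum],
    library: CandidateSet,
    config: Optional[AnnotationConfig] = None,
) -> List[AnnotationRecord]:
    """Run the dereplication cascade over a batch of spectra.

    Deterministic for fixed inputs; shuffling the input order permutes
    but does not change the records (isomer groups are resolved jointly
    across the batch by retention time).
    """
    cfg = config or AnnotationConfig()
    ion = get_ion_species(cfg.precursor_ion)

    trees: Dict[str, FragmentationTree] = {c.name: predict_fragments(c) for c in library}

    viable: Dict[str, List[str]] = {}
    matches: Dict[str, MatchResult] = {}
    records: Dict[str, AnnotationRecord] = {}

    for s in spectra:
        flags: List[str] = []
        fits: List[str] = []
        for c in library:
            theo = ion_mz(c.formula, ion)
            if abs(ppm_error(theo, s.precursor_mz)) > cfg.precursor_ppm_tol:
                continue
            tree = trees[c.name]
            m = match_fragments(tree, s.fragments, cfg.fragment_tol)
            if cfg.require_full_ladder and m.coverage < 1.0:
                continue
            if not _consistent(s, c, tree, cfg, flags):
                continue
            fits.append(c.name)
            matches.setdefault(s.peak_id, m)
        if not fits:
            rec = _class_only_record(s, cfg)
            if flags:
                rec = replace(rec, flags=rec.flags + tuple(flags))
            records[s.peak_id] = rec
            continue
        viable[s.peak_id] = fits
        c0 = library[fits[0]]
        # the record reports the 4-decimal theoretical m/z, and its ppm
        # error is computed against that reported value
        theo = mz_display(ion_mz(c0.formula, ion))
        state = _candidate_calls(trees[fits[0]])
        records[s.peak_id] = AnnotationRecord(
            peak_id=s.peak_id,
            rt_min=s.rt_min,
            assigned_formula=c0.formula,
            selected_ion=ion.label,
            theoretical_mz=theo,
            experimental_mz=s.precursor_mz,
            error_ppm=ppm_error(theo, s.precursor_mz),
            matched_fragment_labels=tuple(matches[s.peak_id].matched_labels),
            skeleton_call=classify_skeleton(s),
            n_hexose_call=c0.n_hexose,
            extra_oh_call=state,
            ene_call=c0.ene_25_27,
            identification=fits[0],
            confidence="tentative",
            flags=tuple(flags),
        )

    # isomer disambiguation: records whose viable candidate sets are equal
    # (same formula, same fragment pattern) form one retention-time group
    groups: Dict[Tuple[str, ...], List[str]] = {}
    for pid, fits in viable.items():
        groups.setdefault(tuple(fits), []).append(pid)
    for fits, pids in groups.items():
        candidates = [library[name] for name in fits]
        group = [records[p] for p in pids]
        if len(group) > 1 or len(candidates) == 1:
            resolved = assign_c25_configuration(group, candidates)
        else:
            # single record, several isobaric candidates: keep library
            # order but mark the identity as class-level only
            resolved = [
                replace(
                    group[0],
                    identification=candidates[0].name,
                    confidence="class-only",
                    flags=group[0].flags + ("isobaric-candidates",),
                )
            ]
        for rec in resolved:
            name = rec.identification
            conf = rec.confidence
            if name in library and conf != "class-only":
                conf = (
                    "standard-confirmed" if library[name].is_standard else "tentative"
                )
            records[rec.peak_id] = replace(rec, confidence=conf)

    return [records[s.peak_id] for s in spectra]
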