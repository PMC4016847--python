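"""Ellman cholinesterase-inhibition assay analytics.

The Ellman assay reads thiocholine production colorimetrically at
412 nm: an inhibited enzyme produces less chromophore, so a lower
optical density (OD) means stronger inhibition. Percent inhibition is
the blank-corrected OD ratio

    inhibition % = (1 - (OD_sample - OD_blank) / (OD_control - OD_blank)) x 100

Replicate percentages are summarised as mean +/- SEM, compared by
one-way ANOVA with Fisher's protected LSD post hoc test, and agents are
ranked by mean inhibition to pick the most active extract or compound.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PlateAssay",
    "InhibitionResult",
    "PairComparison",
    "AnovaLSDResult",
    "AssayError",
    "inhibition_percent",
    "plate_inhibition",
    "assay_inhibition",
    "summarize",
    "anova_lsd",
    "rank_agents",
]


class AssayError(ValueError):
    """Raised for assay failures (bad controls, too few replicates, ...)."""


@dataclass(frozen=True)
class PlateAssay:
    """One replicate plate: an OD well grid with a parallel role grid.

    Roles are "sample", "control" (enzyme, no inhibitor) and "blank"
    (no enzyme). Preincubation timing and temperatures are acquisition
    metadata and never enter the computation.
    """

    readings: np.ndarray
    roles: np.ndarray
    agent_id: str
    enzyme: str  # "AChE" | "BuChE"
    concentration_mg_ml: float
    replicate_index: int = 0
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        readings = np.asarray(self.readings, dtype=float)
        roles = np.asarray(self.roles, dtype=object)
        object.__setattr__(self, "readings", readings)
        object.__setattr__(self, "roles", roles)
        if readings.shape != roles.shape:
            raise AssayError("readings and roles grids must have the same shape")
        if np.any(readings < 0):
            raise AssayError("optical densities must be nonnegative")
        if self.enzyme not in {"AChE", "BuChE"}:
            raise AssayError(f"unknown enzyme {self.enzyme!r}")
        for role in ("control", "blank"):
            if not np.any(roles == role):
                raise AssayError(f"plate has no {role} well")

    def wells(self, role: str) -> np.ndarray:
        return self.readings[self.roles == role]


@dataclass(frozen=True)
class InhibitionResult:
    """Replicate-averaged percent inhibition for one agent and enzyme."""

    agent_id: str
    enzyme: str
    mean_inhibition: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise AssayError("inhibition results require n >= 3 replicates")
        if self.sem < 0:
            raise AssayError("SEM must be nonnegative")

    def display(self) -> str:
        return f"{self.mean_inhibition:.1f} ± {self.sem:.1f}"


def inhibition_percent(
    sample_od: float, control_od: float, blank_od: float = 0.0
) -> float:
    """Blank-corrected percent inhibition from three OD readings.

    Equals 0 when the sample matches the uninhibited control and 100
    when it matches the enzyme-free blank; invariant under rescaling all
    three ODs by a common positive factor. Passing ``blank_od=0`` gives
    the uncorrected raw-ratio convention.
    """
    if control_od <= blank_od:
        raise AssayError(
            f"assay failure: control OD ({control_od}) must exceed blank OD ({blank_od})"
        )
    return (1.0 - (sample_od - blank_od) / (control_od - blank_od)) * 100.0


def plate_inhibition(plate: PlateAssay, blank_corrected: bool = True) -> float:
    """Percent inhibition of one plate: mean sample vs. mean control/blank."""
    control = float(np.mean(plate.wells("control")))
    blank = float(np.mean(plate.wells("blank"))) if blank_corrected else 0.0
    samples = plate.wells("sample")
    if samples.size == 0:
        raise AssayError("plate has no sample wells")
    return float(
        np.mean([inhibition_percent(s, control, blank) for s in samples])
    )


def assay_inhibition(
    plates: Sequence[PlateAssay], blank_corrected: bool = True
) -> InhibitionResult:
    """Summarise replicate plates of one agent into an InhibitionResult."""
    if not plates:
        raise AssayError("no plates given")
    agents = {p.agent_id for p in plates}
    enzymes = {p.enzyme for p in plates}
    if len(agents) != 1 or len(enzymes) != 1:
        raise AssayError("plates must share one agent and one enzyme")
    values = [plate_inhibition(p, blank_corrected) for p in plates]
    return summarize(values, agent_id=plates[0].agent_id, enzyme=plates[0].enzyme)


def summarize(
    values: Sequence[float], agent_id: str = "", enzyme: str = "BuChE"
) -> InhibitionResult:
    """Mean and SEM (sd/sqrt(n)) of replicate inhibition percentages."""
    if len(values) < 3:
        raise AssayError(f"need at least 3 replicates, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    sem = float(np.std(arr, ddof=1) / math.sqrt(len(arr)))
    return InhibitionResult(
        agent_id=agent_id,
        enzyme=enzyme,
        mean_inhibition=float(np.mean(arr)),
        sem=sem,
        n=len(arr),
    )


# --- group comparison -------------------------------------------------------


@dataclass(frozen=True)
class PairComparison:
    agent_a: str
    agent_b: str
    mean_diff: float
    t: float
    p: float
    significant: bool


@dataclass(frozen=True)
class AnovaLSDResult:
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float
    alpha: float
    pairs: Tuple[PairComparison, ...]

    def significant_pairs(self) -> List[Tuple[str, str]]:
        return [(c.agent_a, c.agent_b) for c in self.pairs if c.significant]


def anova_lsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaLSDResult:
    """One-way ANOVA followed by Fisher's protected LSD post hoc test.

    The omnibus F test uses all groups; pairwise comparisons use the
    pooled within-group mean square (t with N - k degrees of freedom)
    and are flagged significant only when both the omnibus test and the
    pairwise test fall below ``alpha`` (the "protected" convention).
    """
    if len(groups) < 2:
        raise AssayError("need at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for name, arr in zip(names, arrays):
        if arr.size < 3:
            raise AssayError(f"group {name!r} has fewer than 3 replicates")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    sse = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if sse == 0.0:
        raise AssayError("degenerate variance: all groups are exactly constant")
    mse = sse / df_within

    f_stat, p_omnibus = stats.f_oneway(*arrays)
    omnibus_sig = bool(p_omnibus < alpha)

    pairs = []
    for (na, a), (nb, b) in itertools.combinations(zip(names, arrays), 2):
        diff = float(a.mean() - b.mean())
        se = math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df_within)
        pairs.append(
            PairComparison(na, nb, diff, t, float(p), omnibus_sig and p < alpha)
        )
    return AnovaLSDResult(
        f=float(f_stat),
        p=float(p_omnibus),
        df_between=k - 1,
        df_within=df_within,
        mse=mse,
        alpha=alpha,
        pairs=tuple(pairs),
    )


def rank_agents(results: Sequence[InhibitionResult]) -> List[InhibitionResult]:
    """Order agents by mean inhibition, strongest first.

    Ties break by ascending SEM (the more precise estimate first), then
    by agent id. All results must concern the same enzyme; the top-ranked
    entry is the screen's selected agent.
    """
    if not results:
        raise AssayError("cannot rank an empty result list")
    enzymes = {r.enzyme for r in results}
    if len(enzymes) != 1:
        raise AssayError(f"results mix enzymes: {sorted(enzymes)}")
    return sorted(
        results,
        key=lambda r: (-r.mean_inhibition, r.sem, r.agent_id),
    )
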