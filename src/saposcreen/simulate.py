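"""Seeded generators for QTOF glycoside spectra and 96-well OD plates.

The spectrum generator emulates what the dereplication cascade assumes
about real data: a sodiated precursor with Gaussian relative (ppm) mass
noise, the predicted neutral-loss fragment ladder with Gaussian absolute
(Da) noise, uniform decoy peaks kept clear of the true ladder, and the
precursor-adduct pattern implied by the skeleton class. Default noise
magnitudes are calibrated to the reference dataset (precursor errors
within ~3 ppm at 2 sigma). The plate generator draws control and sample
wells around the true inhibition with Gaussian OD noise at the SEM
scale the reference screens report.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotate import Spectrum
from .bioassay import PlateAssay
from .fragmentation import predict_fragments
from .library import CandidateSet, SaponinCandidate

__all__ = [
    "SpectrumSimConfig",
    "PlateSimConfig",
    "generate_spectrum",
    "generate_plate",
    "generate_screen",
    "extract_screen_effects",
    "compound_screen_effects",
    "fraction_screen_effects",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Noise model for one simulated saponin MS/MS spectrum."""

    candidate: str
    precursor_ppm_sigma: float = 1.4
    fragment_sigma_da: float = 0.01
    n_decoys: int = 3
    decoy_range: Tuple[float, float] = (150.0, 1000.0)
    decoy_exclusion_da: float = 1.0
    rt_base_min: Optional[float] = None  # default: library reference RT
    rt_jitter_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precursor_ppm_sigma < 0 or self.fragment_sigma_da < 0:
            raise ValueError("noise sigmas must be nonnegative")
        if self.n_decoys < 0:
            raise ValueError("decoy count must be nonnegative")


@dataclass(frozen=True)
class PlateSimConfig:
    """Noise model for replicate Ellman assay plates of one agent."""

    agent_id: str
    enzyme: str
    true_inhibition: float
    control_od_mean: float = 1.0
    blank_od_mean: float = 0.08
    od_sigma: float = 0.02
    n_replicates: int = 6
    wells_per_role: int = 3
    concentration_mg_ml: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_inhibition <= 100.0:
            raise ValueError("true inhibition must be within [0, 100] percent")
        if self.n_replicates < 3:
            raise ValueError("need at least 3 replicates")


def generate_spectrum(cfg: SpectrumSimConfig, library: CandidateSet) -> Spectrum:
    """Simulate one spectrum of a library candidate under the noise model.

    The precursor is the theoretical [M+Na]+ m/z perturbed by a relative
    Normal(0, sigma_ppm^2) error; fragments are the accurate predicted
    protonated-series m/z with Normal(0, sigma_Da^2) noise; decoys are
    uniform over the configured range but rejected within the exclusion
    window of any true ladder ion, so ground truth stays well defined.
    """
    if cfg.candidate not in library:
        raise KeyError(f"unknown candidate {cfg.candidate!r}")
    c = library[cfg.candidate]
    rng = np.random.default_rng(cfg.seed)
    tree = predict_fragments(c)

    sodiated = tree.ion("[M+Na]+").mz
    eps_ppm = rng.normal(0.0, cfg.precursor_ppm_sigma) if cfg.precursor_ppm_sigma else 0.0
    precursor = sodiated * (1.0 + eps_ppm * 1e-6)

    true_mzs = [i.mz for i in tree.protonated_series]
    fragments = [
        mz + (rng.normal(0.0, cfg.fragment_sigma_da) if cfg.fragment_sigma_da else 0.0)
        for mz in true_mzs
    ]

    lo, hi = cfg.decoy_range
    decoys: List[float] = []
    while len(decoys) < cfg.n_decoys:
        x = float(rng.uniform(lo, hi))
        if all(abs(x - t) > cfg.decoy_exclusion_da for t in true_mzs):
            decoys.append(x)
    fragments = sorted(fragments + decoys, reverse=True)

    if c.skeleton == "furostanol" and c.c22_hydroxyl:
        ions_seen = ("[M+Na]+", "[M+H-H2O]+")
    else:
        ions_seen = ("[M+Na]+", "[M+H]+")

    rt_base = cfg.rt_base_min if cfg.rt_base_min is not None else (c.rt_ref or 30.0)
    rt = max(0.0, rt_base + (rng.normal(0.0, cfg.rt_jitter_min) if cfg.rt_jitter_min else 0.0))

    return Spectrum(
        peak_id=f"sim-{c.name}-{cfg.seed}",
        rt_min=rt,
        precursor_mz=precursor,
        precursor_ions_seen=ions_seen,
        fragments=tuple(fragments),
    )


def generate_plate(cfg: PlateSimConfig) -> List[PlateAssay]:
    """Simulate replicate plates of one agent at a known true inhibition.

    Each replicate is a 3 x wells_per_role grid (blank / control /
    sample rows). Blank wells are held at the blank mean; control wells
    are Normal(control mean, sigma^2); sample wells are Normal around
    the OD a perfectly behaving assay would give at the true inhibition.
    """
    rng = np.random.default_rng(cfg.seed)
    c, b = cfg.control_od_mean, cfg.blank_od_mean
    sample_mean = c * (1.0 - cfg.true_inhibition / 100.0) + b * cfg.true_inhibition / 100.0
    plates = []
    for rep in range(cfg.n_replicates):
        blanks = np.full(cfg.wells_per_role, b)
        controls = rng.normal(c, cfg.od_sigma, cfg.wells_per_role) if cfg.od_sigma else np.full(cfg.wells_per_role, c)
        samples = rng.normal(sample_mean, cfg.od_sigma, cfg.wells_per_role) if cfg.od_sigma else np.full(cfg.wells_per_role, sample_mean)
        readings = np.vstack([blanks, controls, samples]).clip(min=0.0)
        roles = np.array(
            [["blank"] * cfg.wells_per_role,
             ["control"] * cfg.wells_per_role,
             ["sample"] * cfg.wells_per_role],
            dtype=object,
        )
        plates.append(
            PlateAssay(
                readings=readings,
                roles=roles,
                agent_id=cfg.agent_id,
                enzyme=cfg.enzyme,
                concentration_mg_ml=cfg.concentration_mg_ml,
                replicate_index=rep,
            )
        )
    return plates


def generate_screen(
    effects: Mapping[str, Mapping[str, Optional[float]]],
    base_config: Optional[PlateSimConfig] = None,
    seed: int = 0,
) -> Dict[Tuple[str, str], List[PlateAssay]]:
    """Simulate a whole screen: plates for every agent x enzyme pair.

    ``effects`` maps agent id -> {enzyme: true inhibition %}; ``None``
    entries mean no detectable activity and are skipped, mirroring how
    inactive agents are reported. Seeds for individual agents are drawn
    deterministically from ``seed``.
    """
    base = base_config or PlateSimConfig(agent_id="", enzyme="BuChE", true_inhibition=0.0)
    root = np.random.default_rng(seed)
    dataset: Dict[Tuple[str, str], List[PlateAssay]] = {}
    for agent in effects:
        for enzyme, truth in effects[agent].items():
            sub_seed = int(root.integers(0, 2**31 - 1))
            if truth is None:
                continue
            cfg = replace(
                base,
                agent_id=agent,
                enzyme=enzyme,
                true_inhibition=truth,
                seed=sub_seed,
            )
            dataset[(agent, enzyme)] = generate_plate(cfg)
    return dataset


# --- packaged effect presets ------------------------------------------------


def extract_screen_effects() -> Dict[str, Dict[str, Optional[float]]]:
    """True-inhibition preset from the packaged crude-extract screen table.

    Agent ids are "solvent/technique"; not-detected cells become None.
    """
    from .io import read_screen_table  # local import to avoid a cycle

    df = read_screen_table("extract_screen")
    effects: Dict[str, Dict[str, Optional[float]]] = {}
    for _, row in df.iterrows():
        agent = f"{row['solvent']}/{row['technique']}"
        effects[agent] = {
            "AChE": None if np.isnan(row["ache_mean"]) else float(row["ache_mean"]),
            "BuChE": None if np.isnan(row["buche_mean"]) else float(row["buche_mean"]),
        }
    return effects


def compound_screen_effects() -> Dict[str, Dict[str, Optional[float]]]:
    """True-inhibition preset from the packaged isolated-compound screen."""
    from .io import read_screen_table

    df = read_screen_table("compound_screen")
    effects: Dict[str, Dict[str, Optional[float]]] = {}
    for _, row in df.iterrows():
        if row.get("role") == "reference":
            continue
        effects[str(row["compound"])] = {
            "AChE": None if np.isnan(row["ache_mean"]) else float(row["ache_mean"]),
            "BuChE": None if np.isnan(row["buche_mean"]) else float(row["buche_mean"]),
        }
    return effects


def fraction_screen_effects() -> Dict[str, Dict[str, Optional[float]]]:
    """Synthetic preset for the resin-column fraction screen.

    The published fraction-level activities exist only as a bar chart,
    so these truths are a synthetic stand-in shaped like that screening
    design: six ethanol/water fractions with the 60% ethanol fraction
    dominant on both enzymes and the water fraction inactive.
    """
    return {
        "0% ethanol (water)": {"AChE": None, "BuChE": None},
        "20% ethanol": {"AChE": 4.0, "BuChE": 16.0},
        "40% ethanol": {"AChE": 11.0, "BuChE": 39.0},
        "60% ethanol": {"AChE": 30.0, "BuChE": 67.0},
        "80% ethanol": {"AChE": 14.0, "BuChE": 33.0},
        "95% ethanol": {"AChE": 6.0, "BuChE": 12.0},
    }
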