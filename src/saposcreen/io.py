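"""Readers and writers for peak tables, spectra, plates and results.

All tabular formats are UTF-8, tab-separated, with '#'-prefixed comment
lines permitted and a decimal point (never a comma). Retention times are
stored in minutes; mzML scan times in seconds are converted on read.
MGF and mzML parsing is delegated to pyteomics.
"""

from __future__ import annotations

import base64
import csv
import logging
import math
import zlib
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import AnnotationRecord, Spectrum
from .bioassay import InhibitionResult, PlateAssay
from .chem import mz_display, ppm_display

logger = logging.getLogger("saposcreen")

__all__ = [
    "PipelineConfig",
    "read_peak_table",
    "write_peak_table",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_annotation_table",
    "read_annotation_table",
    "read_screen_table",
    "screen_results",
    "read_plate",
    "write_plate",
    "builtin_peak_table",
]

PEAK_COLUMNS = ["peak_id", "rt_min", "precursor_mz", "ions_seen", "fragments"]


class TableFormatError(ValueError):
    """Raised for schema or parse errors in tabular inputs."""


def _open_rows(path: Path) -> List[tuple]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        return [
            (row, lineno)
            for lineno, row in enumerate(reader, start=1)
            if row and not row[0].lstrip().startswith("#")
        ]


def read_peak_table(path: str | Path) -> List[Spectrum]:
    """Read a tab-separated peak table into Spectrum objects.

    Schema: peak_id, rt_min, precursor_mz, ions_seen (';'-joined adduct
    labels), fragments (','-joined m/z). Malformed rows raise
    :class:`TableFormatError` naming the offending line.
    """
    path = Path(path)
    rows = _open_rows(path)
    if not rows:
        raise TableFormatError(f"{path}: empty file, expected a header row")
    header, _ = rows[0]
    if header != PEAK_COLUMNS:
        raise TableFormatError(
            f"{path}: bad header {header!r}, expected {PEAK_COLUMNS!r}"
        )
    spectra = []
    for row, lineno in rows[1:]:
        if len(row) != len(PEAK_COLUMNS):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(PEAK_COLUMNS)} columns, got {len(row)}"
            )
        rec = dict(zip(PEAK_COLUMNS, row))
        try:
            spectra.append(
                Spectrum(
                    peak_id=rec["peak_id"],
                    rt_min=float(rec["rt_min"]),
                    precursor_mz=float(rec["precursor_mz"]),
                    precursor_ions_seen=tuple(
                        s.strip() for s in rec["ions_seen"].split(";") if s.strip()
                    ),
                    fragments=tuple(
                        float(f) for f in rec["fragments"].split(",") if f.strip()
                    ),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return spectra


def write_peak_table(spectra: Sequence[Spectrum], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PEAK_COLUMNS)
        for s in spectra:
            w.writerow(
                [
                    s.peak_id,
                    repr(s.rt_min),
                    repr(s.precursor_mz),
                    ";".join(s.precursor_ions_seen),
                    ", ".join(repr(f) for f in s.fragments),
                ]
            )


def builtin_peak_table() -> List[Spectrum]:
    """The packaged 15-peak reference table for the active fraction."""
    with resources.as_file(
        resources.files("saposcreen.data") / "reference_peaks.tsv"
    ) as p:
        return read_peak_table(p)


# --- MGF / mzML -------------------------------------------------------------


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; missing intensities are recorded as 1.0."""
    entries = []
    for s in spectra:
        intensities = (
            s.intensities if s.intensities is not None else tuple(1.0 for _ in s.fragments)
        )
        entries.append(
            {
                "m/z array": np.asarray(s.fragments, dtype=float),
                "intensity array": np.asarray(intensities, dtype=float),
                "params": {
                    "TITLE": s.peak_id,
                    "PEPMASS": s.precursor_mz,
                    "RTINSECONDS": s.rt_min * 60.0,
                    "IONS_SEEN": ";".join(s.precursor_ions_seen),
                },
            }
        )
    _mgf.write(entries, str(path), key_order=["TITLE", "PEPMASS", "RTINSECONDS", "IONS_SEEN"])


def read_mgf(path: str | Path) -> List[Spectrum]:
    """Read an MGF file; RTINSECONDS is converted to minutes on read.

    Entries without a precursor m/z are skipped with a warning.
    """
    spectra = []
    skipped = 0
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                skipped += 1
                continue
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            rt_s = params.get("rtinseconds", 0.0)
            ions = params.get("ions_seen", "")
            spectra.append(
                Spectrum(
                    peak_id=str(params.get("title", f"scan{len(spectra) + 1}")),
                    rt_min=float(rt_s) / 60.0,
                    precursor_mz=precursor,
                    precursor_ions_seen=tuple(
                        s for s in str(ions).split(";") if s
                    ),
                    fragments=tuple(float(x) for x in entry["m/z array"]),
                    intensities=tuple(float(x) for x in entry["intensity array"]),
                )
            )
    if skipped:
        logger.warning("read_mgf: skipped %d entr%s without a precursor m/z",
                       skipped, "y" if skipped == 1 else "ies")
    return spectra


def _decode_binary_array(elem) -> Optional[np.ndarray]:
    """Decode one mzML <binaryDataArray>: base64, 32/64-bit, zlib or raw."""
    params = {_local(c.get("name", "")) for c in elem.iter() if _local(c.tag) == "cvParam"}
    binary = next((c for c in elem.iter() if _local(c.tag) == "binary"), None)
    if binary is None or not (binary.text or "").strip():
        return np.array([], dtype=float)
    raw = base64.b64decode(binary.text.strip())
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_value(elem, name: str):
    for c in elem.iter():
        if _local(c.tag) == "cvParam" and c.get("name") == name:
            return c
    return None


def read_mzml(path: str | Path) -> List[Spectrum]:
    """Read MS2 spectra from an mzML file.

    MS1-only entries are skipped (their count is logged); scan start
    times given in seconds are converted to minutes. Handles 32/64-bit
    float arrays, raw or zlib-compressed.
    """
    spectra: List[Spectrum] = []
    n_ms1 = 0
    tree = ElementTree.parse(str(path))
    for elem in tree.iter():
        if _local(elem.tag) != "spectrum":
            continue
        level = _cv_value(elem, "ms level")
        if level is None or int(level.get("value", "1")) != 2:
            n_ms1 += 1
            continue
        selected = _cv_value(elem, "selected ion m/z")
        if selected is None:
            logger.warning("read_mzml: MS2 scan without precursor skipped")
            continue
        rt = _cv_value(elem, "scan start time")
        if rt is None:
            rt_min = 0.0
        else:
            rt_min = float(rt.get("value", 0.0))
            if rt.get("unitName", "minute") == "second":
                rt_min /= 60.0
        mz_array = intensity_array = None
        for bda in elem.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            names = {
                c.get("name") for c in bda.iter() if _local(c.tag) == "cvParam"
            }
            if "m/z array" in names:
                mz_array = _decode_binary_array(bda)
            elif "intensity array" in names:
                intensity_array = _decode_binary_array(bda)
        if mz_array is None:
            logger.warning("read_mzml: MS2 scan without m/z array skipped")
            continue
        spectra.append(
            Spectrum(
                peak_id=str(elem.get("id", f"scan{len(spectra) + 1}")),
                rt_min=rt_min,
                precursor_mz=float(selected.get("value")),
                precursor_ions_seen=(),
                fragments=tuple(float(x) for x in mz_array),
                intensities=(
                    tuple(float(x) for x in intensity_array)
                    if intensity_array is not None and intensity_array.size == mz_array.size
                    else None
                ),
            )
        )
    if n_ms1:
        logger.warning("read_mzml: skipped %d non-MS2 scan(s)", n_ms1)
    return spectra


# --- annotation tables ------------------------------------------------------

ANNOTATION_COLUMNS = [
    "peak_id",
    "rt_min",
    "formula",
    "selected_ion",
    "theoretical_mz",
    "experimental_mz",
    "error_ppm",
    "fragment_ions",
    "identification",
    "confidence",
    "skeleton_call",
    "n_hexose_call",
]


def write_annotation_table(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    nominal_ladders: Optional[Dict[str, Sequence[int]]] = None,
) -> None:
    """Write annotation records in reference-table column order.

    m/z cells are printed at 4 decimals and ppm errors at 1 decimal;
    fragment ladders as comma-joined integers (supplied per peak via
    ``nominal_ladders``, since records carry labels, not m/z).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for r in records:
            ladder = (nominal_ladders or {}).get(r.peak_id, ())
            w.writerow(
                [
                    r.peak_id,
                    f"{r.rt_min:g}",
                    "" if r.assigned_formula is None else str(r.assigned_formula),
                    r.selected_ion,
                    "" if r.theoretical_mz is None else f"{mz_display(r.theoretical_mz):.4f}",
                    f"{mz_display(r.experimental_mz):.4f}",
                    "" if r.error_ppm is None else f"{ppm_display(r.error_ppm):.1f}",
                    ", ".join(str(int(m)) for m in ladder),
                    r.identification,
                    r.confidence,
                    r.skeleton_call,
                    r.n_hexose_call,
                ]
            )


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an annotation table back as a DataFrame (printed precision)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"peak_id": str, "identification": str},
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing annotation columns {missing}")
    return df


# --- screens and plates -----------------------------------------------------


def read_screen_table(source: str | Path) -> pd.DataFrame:
    """Read a screen summary table (mean/SEM per agent and enzyme).

    ``source`` is a path, or the name of a packaged dataset
    ("extract_screen" or "compound_screen"). 'ND' cells (activity not
    detected) become NaN.
    """
    if isinstance(source, str) and not Path(source).exists():
        with resources.as_file(
            resources.files("saposcreen.data") / f"{source}.tsv"
        ) as p:
            return read_screen_table(p)
    return pd.read_csv(Path(source), sep="\t", comment="#", na_values=["ND"])


def screen_results(
    df: pd.DataFrame, enzyme: str, n: int = 3, include_reference: bool = False
) -> List[InhibitionResult]:
    """Turn a screen summary table into InhibitionResult entries.

    Agents whose activity was not detected for ``enzyme`` are excluded
    rather than scored as zero, and rows marked ``role=reference``
    (positive-control inhibitors such as donepezil) are excluded from
    the screen unless ``include_reference`` is set. ``n`` is the
    replicate count behind the printed mean ± SEM (the screens report
    "at least three").
    """
    col = {"AChE": "ache", "BuChE": "buche"}[enzyme]
    results = []
    for _, row in df.iterrows():
        if "role" in df.columns and row["role"] == "reference" and not include_reference:
            continue
        if math.isnan(row[f"{col}_mean"]):
            continue
        if "compound" in df.columns:
            agent = str(row["compound"])
        else:
            agent = f"{row['solvent']}/{row['technique']}"
        results.append(
            InhibitionResult(
                agent_id=agent,
                enzyme=enzyme,
                mean_inhibition=float(row[f"{col}_mean"]),
                sem=float(row[f"{col}_sem"]),
                n=n,
            )
        )
    return results


def write_plate(plate: PlateAssay, od_path: str | Path, roles_path: str | Path) -> None:
    """Write a plate as two parallel TSV grids (ODs and roles)."""
    np.savetxt(od_path, plate.readings, delimiter="\t", fmt="%.6g")
    with Path(roles_path).open("w", encoding="utf-8") as fh:
        for row in plate.roles:
            fh.write("\t".join(str(r) for r in row) + "\n")


def read_plate(
    od_path: str | Path,
    roles_path: str | Path,
    agent_id: str = "",
    enzyme: str = "BuChE",
    concentration_mg_ml: float = 1.0,
) -> PlateAssay:
    readings = np.atleast_2d(np.loadtxt(od_path, delimiter="\t"))
    with Path(roles_path).open(encoding="utf-8") as fh:
        roles = np.array(
            [line.rstrip("\n").split("\t") for line in fh if line.strip()],
            dtype=object,
        )
    return PlateAssay(
        readings=readings,
        roles=roles,
        agent_id=agent_id,
        enzyme=enzyme,
        concentration_mg_ml=concentration_mg_ml,
    )


# --- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat pipeline configuration, serializable to a key=value file."""

    precursor_ppm_tol: float = 5.0
    fragment_tol_da: float = 0.5
    fragment_tol_ppm: float = 20.0
    alpha: float = 0.05
    inhibition_variant: str = "blank-corrected"  # or "raw-ratio"
    seed: int = 0
    library_path: str = ""

    def __post_init__(self) -> None:
        if min(self.precursor_ppm_tol, self.fragment_tol_da, self.fragment_tol_ppm) <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.inhibition_variant not in {"blank-corrected", "raw-ratio"}:
            raise ValueError(f"unknown inhibition variant {self.inhibition_variant!r}")

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: Dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise TableFormatError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if not hasattr(defaults, key):
                    raise TableFormatError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)
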