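import base64

import numpy as np
import pandas as pd
import pytest
from importlib import resources

import saposcreen as sp


@pytest.fixture(scope="session")
def library():
    return sp.builtin_library()


@pytest.fixture(scope="session")
def peaks():
    return sp.builtin_peak_table()


@pytest.fixture(scope="session")
def reference_table():
    """The packaged reference annotation table (printed-precision values)."""
    with resources.as_file(
        resources.files("saposcreen.data") / "reference_annotations.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"peak_id": str})


def _b64(values):
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def _mzml_spectrum(index, sid, ms_level, mzs, intensities, rt_seconds, precursor=None):
    prec = ""
    if precursor is not None:
        prec = (
            '<precursorList count="1"><precursor>'
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
        )
    return (
        f'<spectrum index="{index}" id="{sid}" defaultArrayLength="{len(mzs)}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>'
        '<scanList count="1"><scan>'
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_seconds}" unitName="second"/>'
        f"</scan></scanList>{prec}"
        '<binaryDataArrayList count="2">'
        '<binaryDataArray><cvParam name="64-bit float"/><cvParam name="no compression"/>'
        f'<cvParam name="m/z array"/><binary>{_b64(mzs)}</binary></binaryDataArray>'
        '<binaryDataArray><cvParam name="64-bit float"/><cvParam name="no compression"/>'
        f'<cvParam name="intensity array"/><binary>{_b64(intensities)}</binary></binaryDataArray>'
        "</binaryDataArrayList></spectrum>"
    )


def write_minimal_mzml(path, spectra):
    """Write a minimal synthetic mzML file for reader tests.

    ``spectra`` is a list of dicts with keys ms_level, mzs, intensities,
    rt_seconds and optional precursor.
    """
    body = "".join(
        _mzml_spectrum(i, f"scan={i + 1}", **s) for i, s in enumerate(spectra)
    )
    xml = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="run1"><spectrumList count="{len(spectra)}">{body}</spectrumList></run></mzML>'
    )
    path.write_text(xml, encoding="utf-8")
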