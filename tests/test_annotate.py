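"""The rule cascade: skeleton calls, ladder counting, epimer resolution."""

import random
from dataclasses import replace

import pytest

import saposcreen as sp
from saposcreen.annotate import (
    AMBIGUOUS,
    FUROSTANOL_C22_OH,
    SPIROSTANOL_TYPE,
    UNDETERMINED,
    AnnotationRecord,
    aglycone_hydroxylation_state,
    assign_c25_configuration,
    classify_skeleton,
    count_hexose_losses,
)
from saposcreen.fragmentation import Tolerance

TOL = Tolerance(da=0.5)


def _spectrum(ions, fragments=(417,), precursor=943.4886, rt=10.0):
    return sp.Spectrum(
        peak_id="s", rt_min=rt, precursor_mz=precursor,
        precursor_ions_seen=tuple(ions), fragments=tuple(float(f) for f in fragments),
    )


class TestSkeletonClassification:
    def test_dehydrated_without_protonated_means_furostanol(self):
        s = _spectrum(["[M+Na]+", "[M+H-H2O]+"])
        assert classify_skeleton(s) == FUROSTANOL_C22_OH

    def test_protonated_ion_means_spirostanol(self):
        s = _spectrum(["[M+H]+", "[M+Na]+"])
        assert classify_skeleton(s) == SPIROSTANOL_TYPE

    def test_sodiated_only_is_undetermined(self):
        assert classify_skeleton(_spectrum(["[M+Na]+"])) == UNDETERMINED

    def test_no_ions_is_an_error(self):
        with pytest.raises(ValueError):
            classify_skeleton(_spectrum([]))


class TestHexoseCounting:
    def test_three_losses_from_dehydrated_root(self):
        assert count_hexose_losses([741, 579, 417], 903.0, TOL) == 3

    def test_two_losses(self):
        assert count_hexose_losses([579, 417], 741.0, TOL) == 2

    def test_empty_fragments(self):
        assert count_hexose_losses([], 903.0, TOL) == 0

    def test_chain_must_be_consecutive(self):
        # missing middle rung stops the count
        assert count_hexose_losses([741, 417], 903.0, TOL) == 1


class TestHydroxylationState:
    def test_bare_aglycone_series(self):
        assert aglycone_hydroxylation_state([417, 273, 255], TOL) == 0

    def test_hydroxylated_series(self):
        assert aglycone_hydroxylation_state([433, 415, 271, 253], TOL) == 1

    def test_unrelated_peaks_undetermined(self):
        assert aglycone_hydroxylation_state([500], TOL) is None

    def test_both_series_is_contradictory(self):
        with pytest.raises(ValueError):
            aglycone_hydroxylation_state([417, 273, 255, 433, 415], TOL)


def _record(peak_id, rt):
    return AnnotationRecord(
        peak_id=peak_id, rt_min=rt, assigned_formula=None, selected_ion="[M+Na]+",
        theoretical_mz=None, experimental_mz=763.4241, error_ppm=None,
        matched_fragment_labels=(), skeleton_call=SPIROSTANOL_TYPE,
        n_hexose_call=2, extra_oh_call=0, ene_call=False,
        identification="", confidence="tentative",
    )


class TestEpimerResolution:
    def test_later_eluting_record_gets_the_25r_epimer(self, library):
        pair = [library["Timosaponin AIII"], library["25R-Timosaponin AIII"]]
        records = [_record("13", 63.9), _record("14", 64.4)]
        out = assign_c25_configuration(records, pair)
        assert [r.identification for r in out] == [
            "Timosaponin AIII", "25R-Timosaponin AIII",
        ]

    def test_swap_applies_when_library_order_puts_r_first(self, library):
        pair = [library["25R-Timosaponin AIII"], library["Timosaponin AIII"]]
        records = [_record("13", 63.9), _record("14", 64.4)]
        out = assign_c25_configuration(records, pair)
        assert [r.identification for r in out] == [
            "Timosaponin AIII", "25R-Timosaponin AIII",
        ]

    def test_singleton_group_unchanged(self, library):
        records = [replace(_record("3", 37.6), identification="x")]
        out = assign_c25_configuration(records, [library["Timosaponin BII"]])
        assert out[0].identification == "Timosaponin BII"

    def test_extra_records_flagged_unresolved(self, library):
        records = [_record("a", 1.0), _record("b", 2.0)]
        out = assign_c25_configuration(records, [library["Timosaponin AI"]])
        assert out[1].identification == "unassigned"
        assert "unresolved-isomer" in out[1].flags


class TestCascade:
    def test_reference_identifications(self, library, peaks, reference_table):
        records = sp.annotate(peaks, library)
        assert [r.identification for r in records] == list(
            reference_table["identification"]
        )

    def test_standards_are_confirmed_others_tentative(self, library, peaks):
        records = {r.peak_id: r for r in sp.annotate(peaks, library)}
        assert records["3"].confidence == "standard-confirmed"
        assert records["4"].confidence == "tentative"
        assert records["8"].confidence == "standard-confirmed"

    def test_input_order_does_not_change_records(self, library, peaks):
        base = {r.peak_id: r for r in sp.annotate(peaks, library)}
        shuffled = list(peaks)
        random.Random(11).shuffle(shuffled)
        for r in sp.annotate(shuffled, library):
            assert r == base[r.peak_id]

    def test_unmatched_precursor_is_unassigned(self, library):
        s = _spectrum(["[M+Na]+"], fragments=[100.0], precursor=500.0)
        rec = sp.annotate([s], library)[0]
        assert rec.identification == "unassigned"
        assert rec.confidence == "class-only"

    def test_contradictory_fragment_series_is_flagged(self, library):
        s = _spectrum(
            ["[M+Na]+", "[M+H-H2O]+"],
            fragments=[903, 741, 579, 417, 273, 255, 433, 415],
        )
        rec = sp.annotate([s], library)[0]
        assert rec.identification == "unassigned"
        assert "ambiguous-hydroxylation-series" in rec.flags

    def test_skeleton_contradiction_blocks_assignment(self, library):
        # BII ladder but a protonated precursor: not a C22-OH furostanol
        s = _spectrum(["[M+Na]+", "[M+H]+"], fragments=[903, 741, 579, 417, 273, 255])
        rec = sp.annotate([s], library)[0]
        assert rec.identification == "unassigned"

    def test_single_spectrum_of_isobaric_group_is_class_only(self, library):
        s = _spectrum(
            ["[M+Na]+", "[M+H-H2O]+"],
            fragments=[903, 741, 579, 417, 273, 255],
            precursor=943.4873,
            rt=38.0,
        )
        rec = sp.annotate([s], library)[0]
        assert rec.identification in {
            "Timosaponin BII", "25R-Timosaponin BII", "25S-Officinalisnin-I",
        }
        assert rec.confidence == "class-only"
        assert "isobaric-candidates" in rec.flags
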