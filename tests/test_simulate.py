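"""Seeded generators: determinism, calibration, noiseless identities."""

import numpy as np
import pytest

import saposcreen as sp
from saposcreen.chem import ppm_error, ion_mz
from saposcreen.fragmentation import predict_fragments


NOISELESS = dict(
    precursor_ppm_sigma=0.0, fragment_sigma_da=0.0, n_decoys=0, rt_jitter_min=0.0
)


class TestSpectrumGenerator:
    def test_fixed_seed_reproduces_byte_identical_spectra(self, library):
        cfg = sp.SpectrumSimConfig(candidate="Timosaponin BII", seed=42)
        assert sp.generate_spectrum(cfg, library) == sp.generate_spectrum(cfg, library)

    def test_different_seeds_differ(self, library):
        a = sp.generate_spectrum(sp.SpectrumSimConfig(candidate="Timosaponin BII", seed=1), library)
        b = sp.generate_spectrum(sp.SpectrumSimConfig(candidate="Timosaponin BII", seed=2), library)
        assert a.precursor_mz != b.precursor_mz

    def test_noiseless_spectrum_is_exact_theory(self, library):
        cfg = sp.SpectrumSimConfig(candidate="Timosaponin BII", **NOISELESS)
        s = sp.generate_spectrum(cfg, library)
        assert round(s.precursor_mz, 4) == 943.4873
        expected = sorted(
            (i.mz for i in predict_fragments(library["Timosaponin BII"]).protonated_series),
            reverse=True,
        )
        assert list(s.fragments) == pytest.approx(expected)

    def test_ions_seen_follow_skeleton_rule(self, library):
        fur = sp.generate_spectrum(
            sp.SpectrumSimConfig(candidate="Timosaponin BII", **NOISELESS), library
        )
        spiro = sp.generate_spectrum(
            sp.SpectrumSimConfig(candidate="Timosaponin AIII", **NOISELESS), library
        )
        assert set(fur.precursor_ions_seen) == {"[M+Na]+", "[M+H-H2O]+"}
        assert set(spiro.precursor_ions_seen) == {"[M+Na]+", "[M+H]+"}

    def test_precursor_ppm_noise_tail_calibration(self, library):
        """At sigma = 5 ppm, ~95% of precursor errors fall within 10 ppm."""
        theo = ion_mz(library["Timosaponin BII"].formula, "[M+Na]+")
        within = 0
        n = 200
        for seed in range(n):
            s = sp.generate_spectrum(
                sp.SpectrumSimConfig(
                    candidate="Timosaponin BII", precursor_ppm_sigma=5.0,
                    fragment_sigma_da=0.0, n_decoys=0, seed=seed,
                ),
                library,
            )
            within += abs(ppm_error(theo, s.precursor_mz)) <= 10.0
        assert 0.90 * n <= within <= 0.99 * n

    def test_decoys_stay_clear_of_true_ladder(self, library):
        tree = predict_fragments(library["Timosaponin G"])
        true_mzs = [i.mz for i in tree.protonated_series]
        s = sp.generate_spectrum(
            sp.SpectrumSimConfig(
                candidate="Timosaponin G", precursor_ppm_sigma=0.0,
                fragment_sigma_da=0.0, n_decoys=25, seed=5,
            ),
            library,
        )
        decoys = [f for f in s.fragments if all(abs(f - t) > 1e-9 for t in true_mzs)]
        assert len(decoys) == 25
        assert all(min(abs(d - t) for t in true_mzs) > 1.0 for d in decoys)

    def test_unknown_candidate_rejected(self, library):
        with pytest.raises(KeyError):
            sp.generate_spectrum(sp.SpectrumSimConfig(candidate="nope"), library)


class TestPlateGenerator:
    def test_noiseless_plate_recovers_truth_exactly(self):
        plates = sp.generate_plate(
            sp.PlateSimConfig(
                agent_id="x", enzyme="BuChE", true_inhibition=75.8,
                od_sigma=0.0, n_replicates=3,
            )
        )
        res = sp.assay_inhibition(plates)
        assert res.mean_inhibition == pytest.approx(75.8, abs=1e-9)
        assert res.sem == pytest.approx(0.0, abs=1e-9)

    def test_zero_inhibition_gives_control_level_samples(self):
        plates = sp.generate_plate(
            sp.PlateSimConfig(
                agent_id="x", enzyme="AChE", true_inhibition=0.0,
                od_sigma=0.0, n_replicates=3,
            )
        )
        p = plates[0]
        assert np.allclose(p.wells("sample"), p.wells("control"))

    def test_noisy_recovery_within_one_point(self):
        """Mean recovered inhibition over 100 seeds within 1 point of truth."""
        errs = []
        for seed in range(100):
            plates = sp.generate_plate(
                sp.PlateSimConfig(
                    agent_id="x", enzyme="BuChE", true_inhibition=44.1,
                    od_sigma=0.02, n_replicates=6, seed=seed,
                )
            )
            errs.append(sp.assay_inhibition(plates).mean_inhibition - 44.1)
        assert abs(np.mean(errs)) < 1.0

    def test_seed_determinism(self):
        cfg = sp.PlateSimConfig(agent_id="x", enzyme="BuChE", true_inhibition=10.0, seed=9)
        a, b = sp.generate_plate(cfg), sp.generate_plate(cfg)
        assert all(np.array_equal(x.readings, y.readings) for x, y in zip(a, b))


class TestScreenGenerator:
    def test_empty_effects_give_empty_dataset(self):
        assert sp.generate_screen({}) == {}

    def test_not_detected_agents_are_skipped(self):
        ds = sp.generate_screen({"x": {"AChE": None, "BuChE": 20.0}}, seed=1)
        assert set(ds) == {("x", "BuChE")}

    def test_extract_preset_reproduces_screen_winner(self):
        ds = sp.generate_screen(sp.extract_screen_effects(), seed=3)
        results = [sp.assay_inhibition(v) for (a, e), v in ds.items() if e == "BuChE"]
        top = sp.rank_agents(results)[0]
        assert top.agent_id == "Ethyl acetate/ultrasonic"

    def test_fraction_preset_selects_dominant_fraction(self):
        ds = sp.generate_screen(sp.fraction_screen_effects(), seed=4)
        results = [sp.assay_inhibition(v) for (a, e), v in ds.items() if e == "BuChE"]
        assert sp.rank_agents(results)[0].agent_id == "60% ethanol"
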