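"""Round-trip validation on seeded synthetic data.

Generates a noisy synthetic spectrum of a known saponin plus replicate
assay plates at a known true inhibition, runs both through their
analysis stages, and prints truth vs. recovery.
"""

from saposcreen import (
    AnnotationConfig,
    PlateSimConfig,
    SpectrumSimConfig,
    Tolerance,
    annotate,
    assay_inhibition,
    builtin_library,
    generate_plate,
    generate_spectrum,
)

library = builtin_library()

# --- spectrum: 5 ppm precursor noise, 0.3 Da fragment noise, 3 decoys
cfg = SpectrumSimConfig(
    candidate="Timosaponin G", precursor_ppm_sigma=5.0,
    fragment_sigma_da=0.3, n_decoys=3, seed=17,
)
s = generate_spectrum(cfg, library)
rec = annotate(
    [s], library,
    AnnotationConfig(precursor_ppm_tol=15.0, fragment_tol=Tolerance(da=1.0)),
)[0]
print(f"simulated candidate : {cfg.candidate}")
print(f"recovered annotation: {rec.identification}")

# --- plates: OD noise sigma 0.02, 6 replicate plates
plates = generate_plate(
    PlateSimConfig(
        agent_id="compound 3", enzyme="BuChE", true_inhibition=75.8,
        od_sigma=0.02, n_replicates=6, seed=17,
    )
)
result = assay_inhibition(plates)
print(f"\ntrue inhibition     : 75.8 %")
print(f"recovered           : {result.display()} % (n={result.n})")
# Recovery within ~1 percentage point shows the assay analytics are
# unbiased at the noise level real plate readings exhibit.
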