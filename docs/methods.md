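# Methods

## Mass arithmetic

All m/z values are exact monoisotopic sums over the elemental
composition, using C 12 (exact), H 1.0078250319, N 14.0030740052,
O 15.9949146221 and Na 22.98976928 Da. One electron mass (0.00054858 Da)
is subtracted per positive charge; every ion in scope is singly charged
(positive-mode ESI only). These constants are needed at ≥6 decimal
places to reproduce 4-decimal adduct masses for molecules near 1 kDa.

The signed mass error is `(theoretical − experimental)/theoretical ×
10⁶` ppm. The sign convention is a package choice (instrument software
varies); it is fixed throughout and reproduces the reference dataset's
printed signs. Report tables print m/z at 4 decimals and ppm at 1
decimal; annotation records carry the 4-decimal theoretical value and
compute their ppm error against it, so the printed error is always
self-consistent with the printed masses. Internals keep full precision.

## The candidate model and fragmentation grammar

A `SaponinCandidate` is a composition, not a structure: aglycone
formula, skeleton class, hexose count, extra-hydroxyl flag, Δ25(27)
flag, C25 configuration. Glucose and galactose are isobaric and carried
only as labels; every glycosidic unit contributes the dehydrated
residue C₆H₁₀O₅ (162.0528 Da). Molecular formula = aglycone + n ×
C₆H₁₀O₅; aglycone formulas in the shipped library were derived by that
subtraction and cross-checked against the fragment-ion compositions the
reference spectra report.

`predict_fragments` expands a small grammar: dehydrated (furostanol) or
protonated (spirostanol) series root, n successive hexose losses, then
E-ring cleavage (C₈H₁₆O₂ saturated / C₈H₁₄O₂ unsaturated) and a final
water loss, with an extra aglycone hydroxyl shifting the deglycosylated
series by +15.9949 Da and inserting a water loss before the cleavage.

Composition alone does not fix the observed pathway for every isobaric
candidate, so the library stores three pathway annotations per entry:

- `dehydration` — `early` (sugar ladder runs from [M+H−H₂O]⁺, the
  common furostanol case), `late` (the ladder retains the 22-OH and
  runs from [M+H]⁺, the water leaving after deglycosylation; the
  dehydrated precursor is still observed in-source), or `none`
  (spirostanol);
- `root_listed` — whether the series root ion itself appears among the
  reported fragments (most spirostanols do not report [M+H]⁺; one
  does);
- `ering_loss` / `extra_h2o_branch` — an override of the E-ring
  composition (one candidate fragments via C₈H₁₈O₂ from a hydroxylated
  side chain, with a separate −H₂O branch) where the default rule does
  not apply.

These annotations are data, set once per candidate from its reference
spectrum; with them the predicted integer ladders reproduce all fifteen
reference fragment lists. Where a reference spectrum's printed accurate
fragment m/z disagrees with its own loss label by >10 mDa (two cases),
the model follows the loss label; nominal ladders are unaffected.

## Matching and the annotation cascade

Fragment matching is greedy nearest-neighbour within a window (absolute
Da or ppm), each observed peak used at most once; coverage is matched /
predicted over the protonated series. Defaults: 5 ppm precursor window
(the reference data's worst |error| is 2.8 ppm), ±0.5 Da fragment
window for unit-precision ladders, 20 ppm for accurate-mass spectra.
All are configuration, not constants; an analysis should run at ~3×
the expected noise σ, which is what the recovery tests do (15 ppm /
±1.0 Da against 5 ppm / 0.3 Da noise).

The cascade per spectrum: (1) formula match on the precursor within the
ppm window; (2) full predicted-ladder coverage required; (3) the
skeleton call from the observed adducts ([M+H]⁺ ⇒ spirostanol-type;
[M+Na]⁺ + [M+H−H₂O]⁺ without [M+H]⁺ ⇒ C22-OH furostanol) and the
hydroxylation-series call (417/273/255 ⇒ bare, 433/415 ⇒ +OH) must not
contradict the candidate — "undetermined" never contradicts, and a
spectrum showing both series is flagged ambiguous, not dropped; (4)
records whose viable candidate sets coincide form one isobaric group,
sorted by retention time and assigned candidates in library (elution)
order, with the constraint that within a 25R/25S pair of the same
parent the 25R epimer takes the later-eluting record. A single record
with several viable isobaric candidates is reported at class-only
confidence. Confidence is otherwise `standard-confirmed` when the
candidate was run as an authentic standard, else `tentative`.

The hexose-count check is a lower bound, not an equality: the terminal
E-ring + H₂O product lies 162.13 Da below the bare aglycone ion, which
unit-precision data cannot distinguish from one further hexose loss
(162.05 Da), so the observed chain can legitimately exceed the
candidate's sugar count. Isobaric library groups share their hexose
count, so no discriminating power is lost. Chain targets are exact
multiples below the root, so one noisy rung does not shift the
windows below it.

## Assay analytics

Percent inhibition is the blank-corrected OD ratio (a `raw-ratio`
variant — blank = 0 — is available in configuration, since published
tables rarely state which convention was used; the blank-corrected form
is standard Ellman practice and anchors 0% at the control and 100% at
the blank). Replicates (n ≥ 3 enforced) are summarised as mean ± SEM
(sd/√n). Group comparison is one-way ANOVA with Fisher's *protected*
LSD: pairwise pooled-MSE t tests at α = 0.05, flagged significant only
when the omnibus F is also significant. "Not detected" screen entries
are excluded from ranking rather than scored as zero, and reference
inhibitors (donepezil) are excluded from screens by default. Ranking is
by mean inhibition, ties broken by SEM then agent id.

## Synthetic data

Spectra: precursor = theoretical [M+Na]⁺ × (1 + ε·10⁻⁶), ε ~ N(0, σ²)
with σ = 1.4 ppm by default (≈95% of draws within the 2.8 ppm envelope
the reference data exhibit); fragments = accurate predicted series m/z
+ N(0, σ_f²), σ_f = 0.01 Da default; decoys uniform over the configured
range, rejected within ±1 Da of any true ladder ion so ground truth
stays well defined; precursor adducts set by the skeleton rule;
retention time = per-candidate reference RT + N(0, 0.2 min). Plates:
blank wells fixed at the blank mean (0.08 OD), control wells N(1.0,
σ²), sample wells N at the OD a perfectly behaved assay would give,
σ = 0.02 OD, 6 replicate plates of 3 wells per role by default. All
generators are pure functions of (config, seed).

What the generators do *not* emulate: chromatographic peak shapes,
isotope envelopes, intensity patterns, in-source fragment overlap
between co-eluting compounds, plate-edge and drift effects. Passing
recovery tests therefore demonstrates the correctness and calibration
of the decision rules under the stated noise model, not robustness to
every real-data artefact.

The fraction-level screen preset is synthetic by construction (the
underlying study reports that screen only graphically): six fractions
with the 60% ethanol fraction dominant, used to exercise the
screen-to-selection path, not to reproduce numbers.

## Problem sizes and determinism

The validation suite uses 200 seeded spectra for annotation recovery,
100 seeds for plate recovery, 30 seeds (×400 permutations) for the
ANOVA/LSD cross-check — sizes at which the binomial uncertainty on the
checked rates is comfortably below the asserted margins while the whole
suite runs in seconds. All stochastic tests are fixed-seed and
therefore deterministic.

## Known limitations

- Composition-level identification only: positional isomers and sugar
  identity are not distinguishable and are reported as the library's
  named placeholder entries where the evidence is ambiguous.
- The elution-order rule resolves epimer pairs only within groups whose
  fragment patterns coincide; it cannot order three or more isomers
  beyond library (elution) order.
- Singly charged positive ions only; no negative mode, no multiply
  charged species, no isotope-pattern scoring.
- Single-concentration percent inhibition only; no IC₅₀ or kinetic
  modelling.
- The mzML reader supports plain or zlib-compressed 32/64-bit float
  arrays (the common case) and reads MS2 scans only.
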