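# saposcreen

Rule-based LC-QTOF-MS dereplication of steroidal saponins coupled to
Ellman cholinesterase-inhibition screening analytics.

## The problem

Bioactivity-guided fractionation of a medicinal plant produces two
intertwined data streams: microplate cholinesterase-inhibition assays
that decide *which* extract or fraction to pursue, and accurate-mass
MS/MS spectra that decide *what* is in the active fraction without
isolating every compound. `saposcreen` implements both halves as a
desk-scale pipeline for steroidal saponin glycosides of the kind found
in *Anemarrhena asphodeloides* rhizome: timosaponins and their C25
epimers.

## The method

**Dereplication.** A saponin candidate is a composition: an aglycone
skeleton (furostanol with a C22 hydroxyl, or spirostanol), *n*
glycosidic hexose units, an optional extra aglycone hydroxyl, and the
C25 configuration. From it the engine predicts the positive-mode
fragmentation tree:

- precursor adducts — [M+Na]⁺ always; C22-hydroxylated furostanols
  dehydrate in-source and show [M+H−H₂O]⁺ instead of [M+H]⁺;
- a ladder of neutral hexose losses, −162.0528 Da per glycosidic bond;
- E-ring cleavage of the bare aglycone ion (−C₈H₁₆O₂ saturated,
  −C₈H₁₄O₂ with Δ25(27) unsaturation) followed by a final −H₂O,
  producing the diagnostic 417/273/255 or 433/415/271/253 ion series.

Theoretical m/z values are exact monoisotopic sums (electron mass
subtracted for cations); assignments are scored by signed mass error,

    ppm = (m/z_theo − m/z_obs) / m/z_theo × 10⁶,

full predicted-ladder coverage in the observed fragments, consistency
of the skeleton/hydroxylation calls, and, for co-isobaric epimer pairs,
elution order on reversed phase (25R elutes after 25S).

**Screening.** Percent inhibition from 412 nm optical densities is the
blank-corrected ratio `(1 − (OD_s − OD_b)/(OD_c − OD_b)) × 100`;
replicates are summarised as mean ± SEM, compared by one-way ANOVA with
Fisher's protected LSD, and agents ranked by mean inhibition.

Seeded generators simulate QTOF spectra (ppm precursor noise, Da
fragment noise, decoy peaks) and OD plates (Gaussian well noise), so
every stage is testable end to end without instrument data.

## Worked example

```bash
python examples/dereplicate_fraction.py
```

prints the annotation of the packaged 15-peak table of the active
fraction, e.g.:

```
peak  RT/min  theor. m/z   ppm  identification
   3    37.6    943.4873  -1.4  Timosaponin BII (standard-confirmed)
   4    38.5    943.4873  -1.0  25R-Timosaponin BII (tentative)
  13    63.9    763.4239  -0.3  Timosaponin AIII (standard-confirmed)
  14    64.4    763.4239  +2.4  25R-Timosaponin AIII (tentative)
```

Each row is one chromatographic peak: the theoretical sodiated m/z of
the assigned formula, the signed mass error against the observed
precursor, and the identification after ladder matching and
elution-order epimer resolution. `examples/rank_screens.py` ranks the
packaged extract and compound screens (ethyl acetate/ultrasonic tops
the extract screen at 44.1 ± 0.5 % BuChE inhibition; compound 3 tops
the compound screen at 75.8 ± 0.7 %), and
`examples/simulate_and_recover.py` shows truth recovery on synthetic
data. A thin CLI mirrors the stages: `saposcreen mass C45H76O19 --ion
'[M+Na]+'`, `saposcreen predict 'Timosaponin BII'`, `saposcreen
annotate peaks.tsv -o out.tsv`, `saposcreen screen-rank
compound_screen`, `saposcreen simulate spectrum ...`.

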