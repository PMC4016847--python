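"""Accurate-mass arithmetic: formula -> adduct m/z -> ppm error.

Computes the theoretical sodiated m/z for timosaponin BII's molecular
formula and the signed ppm error against an observed precursor, the two
numbers an accurate-mass identification hinges on.
"""

from saposcreen import ion_mz, monoisotopic_mass, parse_formula, ppm_error

formula = parse_formula("C45H76O19")  # timosaponin BII, neutral molecule
neutral = monoisotopic_mass(formula)
sodiated = ion_mz(formula, "[M+Na]+")
observed = 943.4886  # experimental precursor m/z for this peak

print(f"neutral monoisotopic mass : {neutral:.4f} Da")
print(f"[M+Na]+ theoretical m/z   : {sodiated:.4f}")
print(f"observed precursor m/z    : {observed:.4f}")
print(f"mass error                : {ppm_error(round(sodiated, 4), observed):+.1f} ppm")
# A |ppm error| under ~3 ppm is what a well-calibrated QTOF delivers and
# is the evidence that the formula assignment is plausible.
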