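"""Predicted MS/MS fragment ladders for saponin glycosides.

For three library candidates, prints the predicted protonated-series
ladder: the in-source water loss (furostanols), successive 162 Da hexose
losses down to the bare aglycone ion, then the E-ring cleavage and a
final water loss. The integer ladder is what an analyst compares against
an MS/MS peak list at unit precision.
"""

from saposcreen import builtin_library, predict_fragments

library = builtin_library()
for name in ["Timosaponin BII", "Timosaponin AIII", "Timosaponin N"]:
    tree = predict_fragments(library[name])
    print(f"\n{name} ({library[name].formula}):")
    for ion in tree.protonated_series:
        print(f"  {ion.mz:9.4f}  {ion.label}")
    print(f"  nominal ladder: {tree.nominal_ladder()}")
# Each printed m/z is the exact monoisotopic value of the labelled ion;
# the nominal ladder is the rounded form annotation tables print.
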