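"""Spectrophotometric enzyme-inhibition percentages.

The activity assay reads p-nitrophenol absorbance at 405 nm; inhibition
is the fractional absorbance drop of the test well relative to the
enzyme-only control: (A_a - A_b) / A_a x 100%.
"""

import ligandfish as lf

wells = [
    ("enzyme-only control", 1.000, 1.000),
    ("strong inhibitor", 1.000, 0.150),
    ("flavone at 5 mM", 1.000, 0.7566),
]
for name, a_a, a_b in wells:
    pct = lf.inhibition_percent(lf.AssayAbsorbance(a_a, a_b))
    print(f"{name:22s} A_a={a_a:.4f} A_b={a_b:.4f} -> inhibition {pct:.2f}%")
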