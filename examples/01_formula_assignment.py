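"""Assign CHO molecular formulas to an accurate mass.

A high-resolution instrument reports the neutral monoisotopic mass of a
screened compound; we enumerate every CHO composition (up to the
extraction ceiling C90 H190 O90) within 5 ppm and inspect the expected
isotope pattern of the best candidate.
"""

import ligandfish as lf

query = 358.1052  # detected MW of a polymethoxyflavone [M+H]+ feature

candidates = lf.enumerate_formulas(query, lf.MassTolerance(5.0))
print(f"query mass {query} Da, {len(candidates)} candidate(s) within 5 ppm:")
for c in candidates:
    print(
        f"  {str(c.formula):12s} theoretical {c.theoretical_mass:.4f} Da  "
        f"{c.ppm_error:+.2f} ppm  RDBE {c.rdbe:.1f}"
    )

best = candidates[0].formula
print(f"\n[M+H]+ of {best}: {lf.mz_from_neutral(lf.monoisotopic_mass(best)):.4f} Th")
print("isotopologue pattern (mass, abundance relative to monoisotopic):")
for mass, rel in lf.isotope_pattern(best, 3):
    print(f"  {mass:.4f} Da  {rel:.4f}")

# The single 5-ppm candidate C19H18O7 with RDBE 11 is the flavone
# skeleton bearing four methoxy and one hydroxy substituent; the ~21%
# A+1 abundance reflects its 19 carbons (19 x 1.07% 13C).
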