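"""Predict molecular formulas for observed precursor masses.

Enumerates all CHNOPS formulas within 5 ppm of an observed [M+H]+ m/z,
ranked by mass error — the step that turns an accurate mass into a
candidate elemental composition.
"""

from camptomine.formula import enumerate_formulas, ion_mz, ppm_error

observations = [
    (161.1069, "tryptamine, the indole-pathway end product"),
    (365.1137, "hydroxycamptothecin isomers (CG5/CG14/VC9)"),
    (517.2181, "strictosidinic acid, the central condensation product"),
]

for mz, label in observations:
    hits = enumerate_formulas(mz, polarity="+", tol_ppm=5.0)
    print(f"m/z {mz}  ({label})")
    for f in hits[:5]:
        err = ppm_error(mz, ion_mz(f, "+"))
        print(f"   {f.hill():14s} {err:+6.2f} ppm  RDBE {f.rdbe():.1f}")
    print()

# The top-ranked formula is the closest in mass among every composition
# inside the element bounds (C<=40, H<=60, N<=4, O<=16, P<=2, S<=2); the
# printed ion formulas of the study's compounds appear in each list.
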