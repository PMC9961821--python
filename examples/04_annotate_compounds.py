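"""Check compound masses and explain MS/MS fragments by neutral losses.

For a few compounds from the packaged ESI-MS/MS table: recompute the
monoisotopic [M-H]- m/z from the elemental formula, compare with the
observed precursor in ppm, and annotate the fragment list with
diagnostic neutral losses (sugar residues, CO, CO2, H2O, ...). Chains
like hexose-then-water show up as multi-step paths.
"""

import extractopt as eo

compounds = eo.load_fixture("table5")
for name in ("Coumalic acid", "Quercetin", "Caffeic acid hexoside"):
    c = next(c for c in compounds if c.name == name)
    calc = eo.adduct_mz(eo.monoisotopic_mass(c.formula), "[M-H]-")
    ppm = eo.ppm_error(c.observed_neg, calc)
    print(f"\n{c.name} ({c.formula}): [M-H]- calc {calc:.4f}, "
          f"observed {c.observed_neg:.4f} ({ppm:+.1f} ppm)")
    hits, misses = eo.annotate_losses(c.observed_neg, c.fragments, tolerance_da=0.02)
    for h in hits:
        print(f"  {h.parent_mz:8.2f} -> {h.fragment_mz:7.2f}  loss {h.loss:12s} "
              f"path {' > '.join(h.path)}")
    if misses:
        print(f"  unexplained fragments: {misses}")
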