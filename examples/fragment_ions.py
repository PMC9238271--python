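"""Fragment-ion m/z of the EntF* metabolite under its disulfide bridge.

The quantifier/qualifier ions used to monitor EntF* in serum are the b2
and b3 fragments; identity confirmation on high-resolution instruments
uses y11 and y12, which both span the Cys6-Cys14 bridge and therefore
sit 2.016 Da below their open-chain values.
"""

from entfkit.peptides import (
    ENTF_STAR,
    Peptide,
    builtin_transition_sets,
    fragment_ion,
    monoisotopic_mass,
)

print(f"{ENTF_STAR.name}: {ENTF_STAR.sequence}, disulfide "
      f"{ENTF_STAR.disulfide_pairs[0][0]}-{ENTF_STAR.disulfide_pairs[0][1]}")
print(f"monoisotopic mass: {monoisotopic_mass(ENTF_STAR):.4f} Da\n")

reduced = Peptide("EntF* (reduced)", ENTF_STAR.sequence)
for series, index in (("b", 2), ("b", 3), ("y", 11), ("y", 12)):
    ion = fragment_ion(ENTF_STAR, series, index)
    open_chain = fragment_ion(reduced, series, index)
    note = "bridged, -2.016 Da" if ion.contains_disulfide else "no bridge in span"
    print(f"{series}{index:<3} m/z = {ion.mz:9.4f}  "
          f"(open chain {open_chain.mz:9.4f}; {note})")

print("\nMRM transition set for serum quantification:")
ts = builtin_transition_sets()["EntF*"]
print(f"precursor m/z {ts.precursor_mz}")
for t in ts.products:
    print(f"  -> {t.product_mz} ({t.collision_energy_ev:.0f} eV, {t.role})")
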