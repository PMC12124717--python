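"""Physical constants and unit conversion factors (CODATA)."""

#: kcal/mol per Hartree
HARTREE_TO_KCALMOL = 627.509474

#: Å per Bohr
BOHR_TO_ANGSTROM = 0.529177211

#: Hartree/Bohr² -> kcal/mol/Å² (for bond force constants, before doubling)
HARTREE_PER_BOHR2_TO_KCAL_PER_ANG2 = HARTREE_TO_KCALMOL / BOHR_TO_ANGSTROM**2
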