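"""Physical constants and unit conversions (CODATA values, Hartree atomic units)."""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
EV_PER_HARTREE = 27.211386
KCALMOL_PER_HARTREE = 627.5094740631
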