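"""Physical constants and unit conventions.

All energies are kcal/mol, distances in angstroms, temperatures in kelvin,
rates in 1/s.  Residue numbering is 1-based inclusive (PPARgamma2 isoform
numbering for the systems this package was written around).
"""

#: Boltzmann constant in kcal/mol/K, the value used throughout for
#: Boltzmann populations and PMF construction.
KB_KCAL_MOL_K: float = 1.9858775e-3

#: Temperature at which well populations are evaluated by default.
DEFAULT_TEMPERATURE_K: float = 298.0
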