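"""Internal unit system and physical constants.

Everything inside the package is expressed in a single unit system:
Angstrom, kcal/mol, kcal/mol/A, ps, amu, Kelvin.  Conversions happen
only at the boundaries (e.g. calculator adapters wrapping eV-based
back ends).
"""

#: 1 eV in kcal/mol.
EV_TO_KCAL = 23.0605

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2 (the MD energy unit).
#: With x in A, m in amu and t in ps, accelerations are
#: a = KCAL_TO_MD * F / m  in A/ps^2 for F in kcal/mol/A.
KCAL_TO_MD = 418.4
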