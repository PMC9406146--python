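"""Physical constants in the unit system used throughout the package.

Energies default to kcal/mol, lengths to angstrom, temperatures to kelvin.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Avogadro constant, exact SI value.
AVOGADRO = 6.02214076e23
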