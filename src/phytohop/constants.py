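"""Physical constants and unit conversions.

Internal units throughout the dynamics code: kcal/mol (energy), angstrom
(length), degree at the API / radian internally (angles), femtosecond (time),
amu (mass), amu*A^2 (torsional inertia).  Electronvolts appear only at the
surface-hopping energy-gap gate.
"""

# Boltzmann constant, kcal/mol/K
KB = 1.987204259e-3

# hbar in (kcal/mol)*fs
HBAR = 15.17872

# 1 eV in kcal/mol (convention fixed for the hop-gap gate)
KCAL_PER_EV = 23.0609

# 1 hartree in kcal/mol (used for the decoherence constant default)
KCAL_PER_HARTREE = 627.5095

# 1 kcal/mol expressed in amu*A^2/fs^2 (kinetic-energy unit of the integrator)
KCAL_TO_AKMA = 1.0 / 2390.057

# convenience: convert amu*A^2/fs^2 -> kcal/mol
AKMA_TO_KCAL = 2390.057
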