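"""Physical constants and unit-conversion factors (CODATA 2018).

Internal unit system: lengths in Å, energies in kcal/mol, masses in amu,
temperatures in K, pressures in MPa, entropies in kcal/mol/K.
"""

# SI
BOLTZMANN_J = 1.380649e-23  # J/K
PLANCK_J = 6.62607015e-34  # J s
HBAR_J = PLANCK_J / (2.0 * 3.141592653589793)
AVOGADRO = 6.02214076e23  # 1/mol
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

# unit conversions
AMU_KG = 1.66053906660e-27
ANGSTROM_M = 1.0e-10
CAL_J = 4.184
KCALMOL_J = 1.0e3 * CAL_J / AVOGADRO  # J per kcal/mol

# Boltzmann constant in kcal/mol/K
KB_KCALMOL = BOLTZMANN_J * AVOGADRO / (1.0e3 * CAL_J)  # 0.0019872...

# Gas constant R = N_A k_B, kcal/mol/K (identical to KB_KCALMOL on the
# molar scale used throughout)
R_KCALMOL = KB_KCALMOL

# Coulomb prefactor: E [kcal/mol] = COULOMB_KCAL * q1*q2 / r[Å]
# for point charges in elementary-charge units in vacuum.
COULOMB_KCAL = 332.0637133

# Debye in C·m
DEBYE_CM = 3.33564e-30
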