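"""Physical constants (CODATA 2018) in the package's internal unit system.

Internal units: lengths in nm, energies in kJ/mol, charges in elementary
charges, temperatures in K.  PDB I/O is in Angstrom.
"""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT = BOLTZMANN * AVOGADRO / 1000.0  # kJ/(mol K) = 8.3145e-3

# Coulomb prefactor e^2 * NA / (4 pi eps0), expressed in kJ * Angstrom / mol
# so that U = COULOMB_KJ_A / r[A] for two unit charges in vacuum.
COULOMB_KJ_A = (
    ELEMENTARY_CHARGE**2
    * AVOGADRO
    / (4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY)
    / 1e-10
    / 1000.0
)  # ~1389.35

ANGSTROM_PER_NM = 10.0
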