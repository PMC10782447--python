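"""Internal unit system and physical constants.

All quantities inside the package are expressed in a self-consistent MD unit
system with O(1) magnitudes:

====================  ==============
length                nm
energy                kJ/mol
time                  ps
mass                  g/mol
charge                elementary charge e
====================  ==============

Derived units follow without conversion factors: force in kJ/(mol nm),
velocity in nm/ps, and conveniently 1 (g/mol)(nm/ps)^2 = 1 kJ/mol, so kinetic
energy is ``0.5*m*v**2`` verbatim.  Conversions to Angstrom and SI diffusion
units (m^2/s) happen only at I/O and reporting boundaries.
"""

# Coulomb constant 1/(4 pi eps0) in kJ/mol * nm / e^2
KE_COULOMB = 138.935458

# Boltzmann constant in kJ/(mol K); k_B * 300 K ~= 2.494 kJ/mol
KB = 8.31446e-3

# Avogadro's number (1/mol)
N_AVOGADRO = 6.02214076e23

# nm^3 -> litres
NM3_TO_L = 1e-24

# nm^2/ps -> m^2/s
NM2_PER_PS_TO_M2_PER_S = 1e-6

# nm <-> Angstrom
NM_TO_ANGSTROM = 10.0
ANGSTROM_TO_NM = 0.1


def thermal_energy(temperature: float) -> float:
    """k_B*T in kJ/mol."""
    return KB * temperature
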