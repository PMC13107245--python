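"""Unit system and physical constants.

One coherent unit system is used throughout the package:
length Å, time fs, mass amu, temperature K, energy kcal/mol,
charge in elementary charges.  Velocities are Å/fs, forces
kcal/(mol·Å), force constants kcal/(mol·Å²) or kcal/(mol·rad²).
"""

import math

import scipy.constants as _c

#: Boltzmann constant, kcal/(mol·K)
KB = 1.987204e-3

#: Coulomb constant 1/(4·pi·eps0), kcal·Å/(mol·e²)
COULOMB = 332.0637

#: Acceleration conversion: 1 kcal/(mol·Å·amu) expressed in Å/fs².
#: a[Å/fs²] = ACC * F[kcal/(mol·Å)] / m[amu]
ACC = 4.184e-4

#: 1 eV in kcal/mol (used for externally quoted chain-of-states tolerances)
EV_TO_KCAL = 23.0609

#: Planck constant over Boltzmann constant, K·s — Eyring prefactor kB*T/h = T/HBAR_OVER_KB
KB_OVER_H = _c.k / _c.h  # s^-1 K^-1

#: Vibrational wavenumber for a force constant of 1 kcal/(mol·Å²) on 1 amu, cm⁻¹.
#: omega[cm⁻¹] = FREQ_CM * sqrt(k[kcal/(mol·Å²)] / m[amu]).
#: Derived: sqrt(4184 J/mol / NA / 1e-20 m² / 1 amu) / (2·pi·c[cm/s]).
FREQ_CM = math.sqrt(4184.0 / _c.N_A / 1e-20 / _c.atomic_mass) / (
    2.0 * math.pi * _c.c * 100.0
)  # ≈ 108.59

#: Pressure unit note: internal pressures are kcal/(mol·Å³); 1 atm ≈ 1.4584e-5 of it.
ATM = 101325.0 * _c.N_A / 4184.0 * 1e-30  # kcal/(mol·Å³)
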