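"""Physical constants and unit conversions.

Internal working units are atomic (bohr, hartree, elementary charge);
every public interface accepts/returns Å, ppm, Hz, cm⁻¹ or nm and
converts here, so a single table owns every factor.
"""

# CODATA 2018
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_EV = 27.211386245988
HARTREE_TO_J = 4.3597447222071e-18
AMU_TO_KG = 1.66053906660e-27
SPEED_OF_LIGHT_CM_S = 2.99792458e10

# planck-relation product: E[eV] * lambda[nm]
EV_NM = 1239.841984
# E[eV] -> wavenumber [cm^-1]
EV_TO_WAVENUMBER = 8065.543937

# sqrt(hartree / (bohr^2 * amu)) expressed as a harmonic wavenumber,
# i.e. nu~ = FREQ_FACTOR_CM * sqrt(lambda) for a mass-weighted Hessian
# eigenvalue lambda in hartree/(bohr^2*amu).  Documented to 10 digits.
_BOHR_M = BOHR_TO_ANGSTROM * 1e-10
import math as _math

HESSIAN_EIGENVALUE_TO_CM = (
    _math.sqrt(HARTREE_TO_J / (_BOHR_M**2 * AMU_TO_KG))
    / (2.0 * _math.pi * SPEED_OF_LIGHT_CM_S)
)  # = 5140.484678 cm^-1
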