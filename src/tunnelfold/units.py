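"""Unit conventions and physical constants.

All lengths are in nanometres, energies in units of kBT at the reference
temperature (298 K), forces in piconewtons and charges in elementary charge
units.  The single conversion constant is ``KBT_PN_NM`` = 4.114 pN·nm, the
thermal energy at 298 K; every force/energy conversion in the package goes
through it.
"""

from __future__ import annotations

import math

#: Thermal energy kBT at the 298 K reference, in pN·nm.
KBT_PN_NM: float = 4.114

#: Elementary charge (C) and vacuum permittivity (F/m), CODATA values.
_E_CHARGE = 1.602176634e-19
_EPS0 = 8.8541878128e-12

#: Coulomb energy of two unit charges 1 nm apart in vacuum, in kBT units:
#: e^2 / (4 pi eps0 * 1 nm) / kBT.  ~56.08 kBT·nm.
COULOMB_KBT_NM: float = (
    _E_CHARGE**2 / (4.0 * math.pi * _EPS0 * 1.0e-9) / (KBT_PN_NM * 1.0e-21)
)

#: Contour length gained per unfolded amino acid, nm.
NM_PER_AA: float = 0.365


def force_times_length_to_kbt(force_pn: float, length_nm: float) -> float:
    """Mechanical work F·x (pN, nm) expressed in kBT."""
    return force_pn * length_nm / KBT_PN_NM


def kbt_to_pn_nm(energy_kbt: float) -> float:
    """Energy in kBT expressed in pN·nm."""
    return energy_kbt * KBT_PN_NM
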