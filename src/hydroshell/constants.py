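"""Physical constants and unit conversions used throughout the package.

Internal units: nm (length), ps (time), amu (mass), elementary charge e,
kJ mol^-1 (energy), K (temperature).  Entropies are handled in nats
internally and reported as -T*S in kJ mol^-1 via ``KB``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant / 1000).
KB: float = 0.0083145

#: Reference temperature, K.
T_REF: float = 300.0

#: Coulomb prefactor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_FACTOR: float = 138.935458

#: Reference pressure, bar.
PRESSURE_REF: float = 1.0

#: 1 bar * 1 nm^3 expressed in kJ mol^-1.
BAR_NM3_TO_KJ_PER_MOL: float = 0.0602214076

# SI constants for the quasi-harmonic (Schlitter) entropy.
HBAR_SI: float = 1.054571817e-34     # J s
KB_SI: float = 1.380649e-23          # J K^-1
AMU_SI: float = 1.66053906660e-27    # kg
AVOGADRO: float = 6.02214076e23      # mol^-1
EULER_E: float = 2.718281828459045

#: Haar volume of the rotation group under the angle-metric normalization.
SO3_VOLUME: float = 78.95683520871486  # 8 * pi^2


@dataclass(frozen=True)
class Constants:
    """Immutable bundle of the constants above, for code that prefers an object."""

    k_B: float = KB
    T_ref: float = T_REF
    coulomb_factor: float = COULOMB_FACTOR
    pressure_ref: float = PRESSURE_REF
    bar_nm3_to_kj_per_mol: float = BAR_NM3_TO_KJ_PER_MOL
    hbar_si: float = HBAR_SI
    k_B_si: float = KB_SI
    amu_si: float = AMU_SI
    N_A: float = AVOGADRO
    euler_e: float = EULER_E
    so3_volume: float = SO3_VOLUME


CONSTANTS = Constants()
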