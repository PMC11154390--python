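"""Molecular-thermodynamic model for the adsorption constant Ka(n).

For short diblock surfactants the adsorption constant deviates from the
simple Traube-rule exponential Ka = delta_a * exp(-Ea/RT): the missing
tail segments suppress adsorption by a factor (1 - exp(-n dmu/RT)).  The
model used here is

    Ka = delta_a * (1 - exp(-n dmu_CF2 / RT)) * exp(-Ea(n)/RT) - n l_CF2,

with the adsorption length

    delta_a = RT l_CF2 / (2 dmu_CF2)

(an order of magnitude below the molecular length, chain-length
independent) and the adsorption free energy

    Ea(n) = -(2 sqrt(3)/pi) alpha gamma0(T) - (n - 1) dmu_CF2 - dmu_CF3.

dmu_CF2 is the free energy of transferring one -CF2- group from oil to
water; the terminal -CF3 group counts double (dmu_CF3 = 2 dmu_CF2, from
its roughly twofold water-contact area), so the chain terms sum to
(n + 1) dmu_CF2.  The first term is the interfacial energy gained by
covering a quasi-hexagonal cell of area (2 sqrt(3)/pi) alpha of the bare
water|hexane interface.  For large n the suppression factor tends to 1
and Davies' expression Ka = delta_a exp(-Ea/RT) is recovered, with the
classic Traube factor Ka(n+1)/Ka(n) = exp(dmu_CF2/RT).

The trailing ``- n l_CF2`` length correction is below 1% of Ka for every
condition studied here; it is kept by default and can be switched off via
``include_length_term=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .exceptions import ValidityError


@dataclass(frozen=True)
class AdsorptionEnergetics:
    """All energetic quantities of the adsorption-constant model."""

    transfer_energy_cf2: float   # dmu_CF2, J/mol
    transfer_energy_cf3: float   # dmu_CF3, J/mol
    adsorption_energy: float     # Ea, J/mol (negative: adsorption favourable)
    adsorption_length: float     # delta_a, m
    adsorption_constant: float   # Ka, m
    n: int
    temperature: float


def adsorption_length(dmu_cf2: float, temperature: float,
                      constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Pre-exponential adsorption length delta_a = RT l_CF2 / (2 dmu_CF2), m."""
    if dmu_cf2 <= 0:
        raise ValidityError(f"dmu_CF2={dmu_cf2} J/mol must be positive")
    rt = constants.gas_constant * temperature
    return rt * constants.segment_height / (2.0 * dmu_cf2)


def adsorption_energy(n: int, dmu_cf2: float, temperature: float,
                      constants: ModelConstants = DEFAULT_CONSTANTS,
                      cf3_ratio: float = 2.0) -> float:
    """Adsorption free energy Ea(n) from water to the water|oil interface, J/mol.

    ``cf3_ratio`` is dmu_CF3/dmu_CF2 (default 2, the contact-area argument).
    """
    if n < 1 or int(n) != n:
        raise ValidityError(f"n={n} must be a positive integer")
    if dmu_cf2 <= 0:
        raise ValidityError(f"dmu_CF2={dmu_cf2} J/mol must be positive")
    interfacial = -constants.hex_coefficient * constants.area_per_mole * \
        constants.gamma0(temperature)
    chain = -(n - 1) * dmu_cf2 - cf3_ratio * dmu_cf2
    return interfacial + chain


def adsorption_constant(n: int, dmu_cf2: float, temperature: float,
                        constants: ModelConstants = DEFAULT_CONSTANTS,
                        cf3_ratio: float = 2.0,
                        include_length_term: bool = True) -> float:
    """Adsorption constant Ka(n), m, including the short-chain suppression."""
    return adsorption_energetics(
        n, dmu_cf2, temperature, constants, cf3_ratio,
        include_length_term).adsorption_constant


def adsorption_energetics(n: int, dmu_cf2: float, temperature: float,
                          constants: ModelConstants = DEFAULT_CONSTANTS,
                          cf3_ratio: float = 2.0,
                          include_length_term: bool = True
                          ) -> AdsorptionEnergetics:
    """Full chain of quantities delta_a, Ea and Ka for one homologue."""
    delta_a = adsorption_length(dmu_cf2, temperature, constants)
    ea = adsorption_energy(n, dmu_cf2, temperature, constants, cf3_ratio)
    rt = constants.gas_constant * temperature
    suppression = -math.expm1(-n * dmu_cf2 / rt)   # 1 - exp(-n dmu/RT)
    ka = delta_a * suppression * math.exp(-ea / rt)
    if include_length_term:
        ka -= n * constants.segment_height
    if ka <= 0:
        raise ValidityError(
            f"Ka={ka} m non-positive for n={n}, dmu_CF2={dmu_cf2} J/mol, "
            f"T={temperature} K — outside the model's physical domain")
    return AdsorptionEnergetics(
        transfer_energy_cf2=dmu_cf2,
        transfer_energy_cf3=cf3_ratio * dmu_cf2,
        adsorption_energy=ea,
        adsorption_length=delta_a,
        adsorption_constant=ka,
        n=n,
        temperature=temperature,
    )
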