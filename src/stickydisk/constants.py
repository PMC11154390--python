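"""Fixed physical parameters of the fluorotelomer-alcohol adsorption model.

The model describes nonionic surfactants F(CF2)nCH2OH adsorbing from water
onto the water|hexane interface.  All quantities are stored in SI units
(J, m, mol, K, N/m); user-facing converters for the conventional units
(mN/m, Angstrom^2, mmol/L) live at the I/O boundary.  The RT0 energy unit
(R x 298.15 K ~ 2.479 kJ/mol) is the standard dimensionless convention for
transfer free energies in this field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .exceptions import ValidityError

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Conversion factor Angstrom^2 -> m^2.
A2_TO_M2 = 1.0e-20

#: Maximum lateral attraction for which the sticky-disk model is valid.
BETA_VALIDITY_LIMIT = 38.0


def area_per_molecule_to_molar(area_A2: float) -> float:
    """Convert a per-molecule cross-section in Angstrom^2 to m^2/mol."""
    return area_A2 * A2_TO_M2 * N_AVOGADRO


def molar_area_to_per_molecule(area_m2_mol: float) -> float:
    """Convert a molar area in m^2/mol to Angstrom^2 per molecule."""
    return area_m2_mol / (A2_TO_M2 * N_AVOGADRO)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the sticky-disk + adsorption-constant model.

    Defaults are the values established for perfluoroalkylated alcohols at
    the water|hexane interface.  The helical-conformation cross section
    (24.5 A^2) is the default parking area; the antiperiplanar alternative
    (21.6 A^2) is provided for sensitivity analysis only.

    Attributes
    ----------
    gas_constant : float
        Universal gas constant R, J/(mol K).
    reference_temperature : float
        T0 used for the RT0 energy unit, K.
    area_cf2_A2 : float
        Cross-sectional (parking) area of a -CF2- segment, A^2/molecule,
        helical conformation.
    area_cf2_antiperiplanar_A2 : float
        Alternative cross section for the distorted antiperiplanar
        conformation, A^2/molecule.
    segment_height : float
        Height l_CF2 of one -CF2- segment along the chain axis, m.
    beta_osmotic : float
        Solvent-depletion (osmotic) contribution to the attraction
        parameter, dimensionless.
    dispersion_constant : float
        Effective London interaction constant L_CF2 for -CF2- pairs
        through hexane, J m^6/mol.
    gamma0_ref : float
        Neat water|hexane interfacial tension at T0, N/m.
    gamma0_slope : float
        Temperature slope of the neat tension, N/(m K); negative.
    """

    gas_constant: float = 8.314
    reference_temperature: float = 298.15
    area_cf2_A2: float = 24.5
    area_cf2_antiperiplanar_A2: float = 21.6
    segment_height: float = 1.306e-10
    beta_osmotic: float = 0.17
    dispersion_constant: float = 6.32e-54
    gamma0_ref: float = 50.56e-3
    gamma0_slope: float = -0.0876e-3

    def __post_init__(self) -> None:
        for name in ("gas_constant", "reference_temperature", "area_cf2_A2",
                     "segment_height", "gamma0_ref"):
            if getattr(self, name) <= 0:
                raise ValidityError(f"{name} must be positive")
        if self.dispersion_constant < 0:  # zero switches dispersion off
            raise ValidityError("dispersion_constant must be non-negative")
        if self.gamma0_slope >= 0:
            raise ValidityError("gamma0_slope must be negative (tension falls with T)")
        if not 0.0 <= self.beta_osmotic < BETA_VALIDITY_LIMIT:
            raise ValidityError(
                f"beta_osmotic={self.beta_osmotic} outside the sticky-disk "
                f"validity range [0, {BETA_VALIDITY_LIMIT})")

    # -- derived conveniences ------------------------------------------------

    @property
    def rt0(self) -> float:
        """The RT0 energy unit, J/mol."""
        return self.gas_constant * self.reference_temperature

    @property
    def area_per_mole(self) -> float:
        """Parking area alpha = N_A * alpha_CF2, m^2/mol (enters alpha*Gamma)."""
        return area_per_molecule_to_molar(self.area_cf2_A2)

    @property
    def segment_radius(self) -> float:
        """Effective hard-disk radius R_CF2 = sqrt(alpha_CF2/pi), m."""
        return math.sqrt(self.area_cf2_A2 * A2_TO_M2 / math.pi)

    @property
    def hex_coefficient(self) -> float:
        """Quasi-hexagonal packing ratio 2*sqrt(3)/pi ~ 1.1027.

        Ratio of the hexagonal cell area per molecule in a close-packed
        mixed monolayer to the hard-disk area; multiplies alpha*gamma0 in
        the interfacial work term of the adsorption free energy.
        """
        return 2.0 * math.sqrt(3.0) / math.pi

    def gamma0(self, temperature: float) -> float:
        """Interfacial tension of the neat water|hexane interface, N/m.

        Linear correlation gamma0(T) = gamma0_ref + slope*(T - T0),
        valid over the liquid range of the interface.  Temperatures far
        outside the measured 288-303 K window trigger a warning.

        Parameters
        ----------
        temperature : float
            Absolute temperature, K.
        """
        if temperature <= 0:
            raise ValidityError(f"non-physical temperature {temperature} K")
        if not 273.0 < temperature < 373.0:
            warnings.warn(
                f"T={temperature} K outside the liquid water|hexane range; "
                "the gamma0 correlation is an extrapolation", stacklevel=2)
        return self.gamma0_ref + self.gamma0_slope * (
            temperature - self.reference_temperature)

    # -- config-file override ------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConstants":
        """Build constants from a ``key = value`` text file.

        Unknown keys raise; missing keys keep their defaults.  Values are
        in the same units as the dataclass fields (SI, except the areas
        which are A^2/molecule as documented).
        """
        known = {f.name for f in fields(cls)}
        overrides: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown constant {key!r}")
            overrides[key] = float(value)
        return cls(**overrides)

    def with_antiperiplanar_area(self) -> "ModelConstants":
        """Variant using the antiperiplanar cross section (sensitivity)."""
        return replace(self, area_cf2_A2=self.area_cf2_antiperiplanar_A2)


#: Package-wide default constants.
DEFAULT_CONSTANTS = ModelConstants()


def gamma0(temperature: float,
           constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Neat water|hexane interfacial tension at ``temperature``, N/m."""
    return constants.gamma0(temperature)


@dataclass(frozen=True)
class Surfactant:
    """A fluorotelomer alcohol F(CF2)nCH2OH identified by its tail length.

    The perfluorinated tail has ``n`` carbons; the alpha-carbon methylene
    behaves as part of the polar group and does not count.
    """

    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValidityError(f"tail length n={self.n} must be a positive integer")
        if not self.label:
            object.__setattr__(self, "label", default_label(self.n))


def default_label(n: int) -> str:
    """Conventional condensed formula for the n-th fluorotelomer alcohol."""
    if n == 1:
        return "CF3CH2OH"
    return f"CF3(CF2){n - 1}CH2OH"
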