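"""Synthetic tensiometry: isotherm datasets with the study's error structure.

The generator emulates the design of the drop-profile tensiometry
experiment: for each homologue the top concentration sits where the
forward model predicts a chosen anchor pressure (standing in for "near
the solubility limit"), two further points follow by twofold and fourfold
dilution, and every pressure carries independent Gaussian noise with the
experimentally determined standard deviation 0.26 mN/m.  An optional
trace-impurity mechanism co-adsorbs a second homologue (chain offset +1,
mole fraction <= 3%) in a mixed sticky-disk monolayer sharing one parking
area and attraction parameter — a beyond-measurement realism device used
only for directional robustness checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import ka_model, monolayer
from .cohesion import beta_parameter
from .constants import DEFAULT_CONSTANTS, ModelConstants, Surfactant
from .exceptions import (CoverageError, DesignError, NoSolutionError,
                         ValidityError)
from .inference import IsothermDataset, model_pressures

logger = logging.getLogger(__name__)

#: Default anchor surface pressure for the top concentration, N/m.
DEFAULT_TARGET_PRESSURE = 15.0e-3

#: Default Gaussian noise on each pressure, N/m (tensiometer repeatability).
DEFAULT_NOISE_SD = 0.26e-3

#: Vendor-reported ceiling on the trace-impurity mole fraction.
MAX_IMPURITY_FRACTION = 0.03


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one synthetic tensiometry campaign.

    Defaults reproduce the study conditions: homologues n = 2 and 3,
    three concentrations per surfactant (top, /2, /4), homoscedastic
    Gaussian pressure noise of 0.26 mN/m, no impurity.
    """

    surfactants: tuple[Surfactant, ...] = (Surfactant(2), Surfactant(3))
    temperatures: tuple[float, ...] = (293.15,)
    dilution_factors: tuple[float, ...] = (1.0, 2.0, 4.0)
    target_pressure: float = DEFAULT_TARGET_PRESSURE
    noise_sd: float = DEFAULT_NOISE_SD
    impurity_fraction: float = 0.0
    impurity_chain_offset: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.surfactants or not self.temperatures:
            raise DesignError("need at least one surfactant and one temperature")
        d = np.asarray(self.dilution_factors, dtype=float)
        if d.size == 0 or d[0] != 1.0 or np.any(d <= 0):
            raise DesignError("dilution_factors must be positive and start at 1")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be non-negative")
        if not 0.0 <= self.impurity_fraction <= MAX_IMPURITY_FRACTION:
            raise DesignError(
                f"impurity_fraction must lie in [0, {MAX_IMPURITY_FRACTION}]")
        if not 0.0 < self.target_pressure:
            raise DesignError("target_pressure must be positive")


def choose_top_concentration(surfactant: Surfactant, temperature: float,
                             target_pressure: float, dmu_cf2: float,
                             constants: ModelConstants = DEFAULT_CONSTANTS,
                             beta: float | None = None,
                             cf3_ratio: float = 2.0,
                             include_length_term: bool = True) -> float:
    """Concentration (mol/m^3) at which the forward model hits a pressure.

    Inverts the forward model exactly: Pi -> Gamma -> fa -> C = fa*Gamma/Ka.
    Returns 0 for a zero target.
    """
    if target_pressure < 0 or target_pressure >= constants.gamma0(temperature):
        raise DesignError(
            f"target pressure {target_pressure} N/m outside "
            f"[0, gamma0={constants.gamma0(temperature)} N/m)")
    if target_pressure == 0.0:
        return 0.0
    if beta is None:
        beta = beta_parameter(surfactant.n, temperature, constants).beta_total
    ka = ka_model.adsorption_constant(surfactant.n, dmu_cf2, temperature,
                                      constants, cf3_ratio, include_length_term)
    params = monolayer.MonolayerParams(
        area=constants.area_per_mole, beta=beta, ka=ka,
        temperature=temperature, gas_constant=constants.gas_constant)
    gamma_ads = monolayer.invert_eos(target_pressure, params)
    fa = monolayer.activity_coefficient(gamma_ads, params)
    return fa * gamma_ads / ka


def mixed_monolayer_pressures(concentrations: Sequence[float],
                              n_main: int, n_impurity: int,
                              impurity_fraction: float,
                              dmu_cf2: float, temperature: float,
                              beta: float,
                              constants: ModelConstants = DEFAULT_CONSTANTS,
                              cf3_ratio: float = 2.0,
                              include_length_term: bool = True) -> np.ndarray:
    """Pressures for a main surfactant carrying a trace co-adsorbing impurity.

    Both species share the parking area and attraction parameter; each
    obeys Ka_i*C_i = fa(total coverage)*Gamma_i, so the total adsorption
    solves Gamma_tot*fa(Gamma_tot) = sum_i Ka_i*C_i and the pressure is
    the sticky-disk pressure at the total coverage.
    """
    ka_main = ka_model.adsorption_constant(n_main, dmu_cf2, temperature,
                                           constants, cf3_ratio,
                                           include_length_term)
    ka_imp = ka_model.adsorption_constant(n_impurity, dmu_cf2, temperature,
                                          constants, cf3_ratio,
                                          include_length_term)
    params = monolayer.MonolayerParams(
        area=constants.area_per_mole, beta=beta, ka=1.0,
        temperature=temperature, gas_constant=constants.gas_constant)
    out = []
    for c in concentrations:
        # effective single-species problem with Ka*C -> sum of Ka_i*C_i
        target = ka_main * (1.0 - impurity_fraction) * c \
            + ka_imp * impurity_fraction * c
        eta = monolayer.solve_isotherm_coverage(target, params)
        out.append(monolayer.surface_pressure(eta / params.area, params))
    return np.asarray(out)


def generate_isotherms(design: ExperimentDesign,
                       true_dmu_cf2: float | Mapping[float, float],
                       constants: ModelConstants = DEFAULT_CONSTANTS,
                       rng: np.random.Generator | None = None,
                       cf3_ratio: float = 2.0,
                       include_length_term: bool = True
                       ) -> list[IsothermDataset]:
    """Generate one synthetic campaign as a list of isotherm datasets.

    ``true_dmu_cf2`` is either a single energy (J/mol) or a mapping from
    temperature to energy.  Deterministic for a fixed ``design.seed`` (or
    a supplied ``rng``).  Noisy pressures are clipped at zero; clipping
    events are logged.  A design whose top concentration would push the
    coverage towards the hard-disk bound raises ``DesignError``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    datasets: list[IsothermDataset] = []
    for temperature in design.temperatures:
        if isinstance(true_dmu_cf2, Mapping):
            try:
                dmu = true_dmu_cf2[temperature]
            except KeyError as exc:
                raise DesignError(
                    f"no true dmu_CF2 supplied for T={temperature} K") from exc
        else:
            dmu = float(true_dmu_cf2)
        if dmu <= 0:
            raise ValidityError("true dmu_CF2 must be positive")
        for surf in design.surfactants:
            beta = beta_parameter(surf.n, temperature, constants).beta_total
            top = choose_top_concentration(
                surf, temperature, design.target_pressure, dmu, constants,
                beta, cf3_ratio, include_length_term)
            conc = np.sort(top / np.asarray(design.dilution_factors))
            try:
                if design.impurity_fraction > 0:
                    clean = mixed_monolayer_pressures(
                        conc, surf.n, surf.n + design.impurity_chain_offset,
                        design.impurity_fraction, dmu, temperature, beta,
                        constants, cf3_ratio, include_length_term)
                else:
                    clean = model_pressures(
                        conc, surf.n, dmu, temperature, beta, constants,
                        cf3_ratio, include_length_term)
            except (CoverageError, NoSolutionError) as exc:
                raise DesignError(
                    f"design unphysical at T={temperature} K, n={surf.n}, "
                    f"top concentration {top} mol/m^3: {exc}") from exc
            noisy = clean + rng.normal(0.0, design.noise_sd, size=clean.shape)
            n_clipped = int(np.sum(noisy < 0))
            if n_clipped:
                logger.info("clipped %d negative pressure(s) at T=%s K, n=%d",
                            n_clipped, temperature, surf.n)
            noisy = np.clip(noisy, 0.0, None)
            gamma0 = constants.gamma0(temperature)
            if np.any(noisy >= gamma0):
                raise DesignError(
                    f"design yields Pi >= gamma0 at T={temperature} K, "
                    f"n={surf.n}, top concentration {top} mol/m^3")
            datasets.append(IsothermDataset(
                surfactant=surf, temperature=temperature,
                concentrations=tuple(conc), pressures=tuple(noisy),
                gamma0_used=gamma0,
                provenance=(f"synthetic: dmu_CF2={dmu} J/mol, beta={beta:.4f},"
                            f" noise_sd={design.noise_sd} N/m, "
                            f"impurity={design.impurity_fraction}, "
                            f"seed={design.seed}")))
    return datasets
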