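"""Sticky-disk (SD) equation of state for a fluid surfactant monolayer.

The SD model is a hard-disk (scaled-particle) monolayer equation of state
augmented with a one-dimensional sticky attraction of strength ``beta``.
It relates the adsorption Gamma (mol/m^2), the surface pressure
Pi = gamma0 - gamma (N/m), and — through the associated surface activity
coefficient ``fa`` and the adsorption isotherm Ka*C = fa*Gamma — the bulk
concentration C (mol/m^3).

The equation of state and the activity coefficient form a Gibbs-consistent
pair: dPi/dGamma = RT * Gamma * d ln(fa*Gamma)/dGamma, which the test
suite verifies numerically.  At beta -> 0 both reduce analytically to the
scaled-particle hard-disk expressions, used here as the small-beta branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import BETA_VALIDITY_LIMIT
from .exceptions import CoverageError, NoSolutionError, ValidityError

#: Below this beta the analytic hard-disk limit expressions are used;
#: (R_beta - 1)/beta and the (2 + 1/beta) exponent are 0/0-singular at 0.
SMALL_BETA = 1.0e-6

#: Upper end of the coverage bracket used by the numerical inversions.
ETA_MAX = 1.0 - 1.0e-6


@dataclass(frozen=True)
class MonolayerParams:
    """The sticky-disk parameter triplet plus temperature.

    Attributes
    ----------
    area : float
        Parking area alpha per mole of surfactant, m^2/mol.
    beta : float
        Dimensionless lateral attraction; must satisfy 0 <= beta < 38
        (the model fails for strongly cohesive monolayers).
    ka : float
        Adsorption constant, m (Henry-law slope Gamma/C at infinite
        dilution, with C in mol/m^3).
    temperature : float
        Absolute temperature, K.
    """

    area: float
    beta: float
    ka: float
    temperature: float
    gas_constant: float = 8.314

    def __post_init__(self) -> None:
        if self.area <= 0 or self.ka <= 0 or self.temperature <= 0:
            raise ValidityError("area, ka and temperature must be positive")
        if self.beta < 0:
            raise ValidityError(f"beta={self.beta} must be non-negative")
        if self.beta >= BETA_VALIDITY_LIMIT:
            raise ValidityError(
                f"beta={self.beta} >= {BETA_VALIDITY_LIMIT}: the sticky-disk "
                "model does not describe strongly cohesive monolayers")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class MonolayerState:
    """Full thermodynamic state of the monolayer at one concentration."""

    adsorption: float          # Gamma, mol/m^2
    coverage: float            # eta = alpha * Gamma
    surface_pressure: float    # Pi, N/m
    activity_coefficient: float
    r_beta: float
    concentration: float | None = None   # bulk C, mol/m^3, when known


def _check_coverage(eta: float) -> None:
    if eta < 0:
        raise CoverageError(f"negative adsorption (eta={eta})")
    if eta >= 1.0:
        raise CoverageError(f"coverage eta={eta} >= 1 violates the hard-disk bound")


def r_beta(adsorption: float, params: MonolayerParams) -> float:
    """Auxiliary R_beta = sqrt(1 + 4*beta*eta/(1-eta)); equals 1 at Gamma=0."""
    eta = params.area * adsorption
    _check_coverage(eta)
    return math.sqrt(1.0 + 4.0 * params.beta * eta / (1.0 - eta))


def surface_pressure(adsorption: float, params: MonolayerParams) -> float:
    """Surface pressure Pi(Gamma) of the sticky-disk monolayer, N/m.

    Pi = RT (R_beta - 1) / (2 alpha beta (1 - eta)); for beta below
    ``SMALL_BETA`` the analytic hard-disk limit RT*Gamma/(1-eta)^2 is used
    (continuous across the switch).
    """
    eta = params.area * adsorption
    _check_coverage(eta)
    if params.beta < SMALL_BETA:
        return params.rt * adsorption / (1.0 - eta) ** 2
    rb = r_beta(adsorption, params)
    return params.rt * (rb - 1.0) / (2.0 * params.area * params.beta * (1.0 - eta))


def log_activity_coefficient(adsorption: float,
                             params: MonolayerParams) -> float:
    """ln fa(Gamma); finite where fa itself would overflow (eta -> 1)."""
    eta = params.area * adsorption
    _check_coverage(eta)
    if eta == 0.0:
        return 0.0
    one_m = 1.0 - eta
    if params.beta < SMALL_BETA:
        return (-math.log(one_m) - eta / one_m
                + eta * (4.0 - 3.0 * eta) / one_m ** 2)
    rb = r_beta(adsorption, params)
    half = 2.0 / (1.0 + rb)
    return (-math.log(one_m)
            + (2.0 + 1.0 / params.beta) * math.log(half)
            + eta * (4.0 - 3.0 * eta) / one_m ** 2 * half)


def activity_coefficient(adsorption: float, params: MonolayerParams) -> float:
    """Surface activity coefficient fa(Gamma) of the adsorbed surfactant.

    fa = [1/(1-eta)] [2/(1+R_beta)]^(2+1/beta)
         * exp[ eta(4-3 eta)/(1-eta)^2 * 2/(1+R_beta) ],
    with the analytic beta -> 0 limit
    fa = [1/(1-eta)] exp[-eta/(1-eta) + eta(4-3 eta)/(1-eta)^2]
    below ``SMALL_BETA``.  fa(0) = 1.
    """
    return math.exp(log_activity_coefficient(adsorption, params))


def max_surface_pressure(params: MonolayerParams, eta_max: float = ETA_MAX) -> float:
    """Largest pressure attainable on the physical branch (at eta_max)."""
    return surface_pressure(eta_max / params.area, params)


def invert_eos(pressure: float, params: MonolayerParams,
               rtol: float = 1.0e-10, eta_max: float = ETA_MAX) -> float:
    """Invert Pi(Gamma) on the physical (monotone) branch.

    Returns the unique adsorption Gamma with surface_pressure(Gamma) equal
    to ``pressure``, by bracketed root finding on eta in [0, eta_max].
    The hard-disk EOS diverges towards close packing, so with the default
    ``eta_max`` almost any pressure is formally attainable; callers with a
    physical ceiling (e.g. Pi < gamma0 in measured isotherms) can tighten
    ``eta_max``.

    Raises
    ------
    NoSolutionError
        If ``pressure`` exceeds the attainable maximum on [0, eta_max]
        (reported in the message) or is negative.
    """
    if pressure < 0:
        raise NoSolutionError(f"negative surface pressure {pressure} N/m")
    if pressure == 0.0:
        return 0.0
    pi_max = max_surface_pressure(params, eta_max)
    if pressure > pi_max:
        raise NoSolutionError(
            f"Pi={pressure:.6g} N/m unattainable; maximum on the physical "
            f"branch (eta <= {eta_max}) is {pi_max:.6g} N/m")

    def residual(eta: float) -> float:
        return surface_pressure(eta / params.area, params) - pressure

    eta = brentq(residual, 0.0, eta_max, xtol=1e-16, rtol=max(rtol, 1e-15))
    return eta / params.area


def solve_isotherm_coverage(target: float, params: MonolayerParams) -> float:
    """Coverage eta solving fa(Gamma)*Gamma = target (mol/m^2).

    Works in log space so the astronomically large fa near close packing
    cannot overflow.  ``target`` is Ka*C for a single surfactant, or the
    sum of Ka_i*C_i for a mixed monolayer with shared area and beta.
    """
    if target < 0:
        raise ValidityError(f"negative isotherm target {target}")
    if target == 0.0:
        return 0.0
    log_target = math.log(target)

    def log_residual(eta: float) -> float:
        gamma_ads = eta / params.area
        return (log_activity_coefficient(gamma_ads, params)
                + math.log(gamma_ads) - log_target)

    lo = 1.0e-18
    if log_residual(lo) >= 0:
        # Henry regime below the bracket floor: fa = 1 to ~1e-18.
        return params.area * target
    hi = ETA_MAX
    if log_residual(hi) < 0:
        raise NoSolutionError(
            f"Ka*C={target:.6g} mol/m^2 exceeds fa*Gamma at eta={hi}; "
            f"check beta={params.beta} and the model validity range")
    return brentq(log_residual, lo, hi, xtol=1e-18, rtol=1e-15)


def equilibrium_state(concentration: float,
                      params: MonolayerParams) -> MonolayerState:
    """Solve the adsorption isotherm Ka*C = fa(Gamma)*Gamma for Gamma.

    Assumes an ideal bulk solution (unit bulk activity coefficient).  The
    product fa*Gamma is strictly increasing in Gamma on the physical
    branch for moderate beta, so the root is unique; it is found by
    bracketed root finding on eta in [0, ETA_MAX).  Returns the full
    monolayer state including the surface pressure.
    """
    if concentration < 0:
        raise ValidityError(f"negative concentration {concentration}")
    if concentration == 0.0:
        return MonolayerState(0.0, 0.0, 0.0, 1.0, 1.0, concentration=0.0)
    eta = solve_isotherm_coverage(params.ka * concentration, params)
    gamma_ads = eta / params.area
    return MonolayerState(
        adsorption=gamma_ads,
        coverage=eta,
        surface_pressure=surface_pressure(gamma_ads, params),
        activity_coefficient=activity_coefficient(gamma_ads, params),
        r_beta=r_beta(gamma_ads, params),
        concentration=concentration,
    )
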