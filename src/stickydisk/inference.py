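"""Transfer-energy estimation from interfacial-pressure isotherms.

Two estimators are provided for the -CF2- oil-to-water transfer energy
dmu_CF2:

* ``per_point_transfer_energy`` — the diagnostic estimator: each measured
  (C, Pi) point is inverted through the chain
  Pi -> Gamma (equation of state) -> fa (activity coefficient)
  -> Ka = fa*Gamma/C (isotherm) -> dmu_CF2 (adsorption-constant model).

* ``fit_transfer_energy`` — the production estimator: all points of all
  homologues at one temperature are fitted simultaneously with a single
  dmu_CF2 by damped (Levenberg-Marquardt) least squares on the surface
  pressures, with a Jacobian-based standard error.

The n = 1 homologue (trifluoroethanol) is excluded from the simultaneous
fit by default: the adsorption-constant model is inadequate for the first
member of the series, whose terminal CF3 group interacts with the aqueous
phase and likely adsorbs with a more horizontal orientation.

``thermo_decomposition`` regresses fitted energies against temperature to
split dmu_CF2 = dh - T*ds into temperature-independent enthalpic and
entropic parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from . import ka_model, monolayer
from .cohesion import beta_parameter
from .constants import DEFAULT_CONSTANTS, ModelConstants, Surfactant
from .exceptions import (AmbiguityError, NoSolutionError, StickyDiskError,
                         ValidityError)

#: Search bracket for dmu_CF2, in RT0 units (covers every literature value).
DMU_BRACKET_RT0 = (0.5, 4.0)

#: Default initial guess for the simultaneous fit, in RT0 units.
DMU_INITIAL_RT0 = 1.7


@dataclass(frozen=True)
class IsothermDataset:
    """Equilibrium isotherm of one surfactant at one temperature.

    ``concentrations`` are bulk aqueous values in mol/m^3 (== mmol/L),
    strictly increasing; ``pressures`` are surface pressures Pi in N/m,
    each in [0, gamma0).
    """

    surfactant: Surfactant
    temperature: float
    concentrations: tuple[float, ...]
    pressures: tuple[float, ...]
    gamma0_used: float
    provenance: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        if c.size == 0 or c.size != p.size:
            raise ValidityError("concentrations and pressures must be "
                                "non-empty and of equal length")
        if np.any(c <= 0):
            raise ValidityError("all concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValidityError("concentrations must be strictly increasing")
        if np.any(p < 0) or np.any(p >= self.gamma0_used):
            raise ValidityError(
                "surface pressures must satisfy 0 <= Pi < gamma0 "
                f"(gamma0={self.gamma0_used} N/m)")
        if self.temperature <= 0:
            raise ValidityError("temperature must be positive")
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))
        object.__setattr__(self, "pressures", tuple(float(x) for x in p))

    @property
    def n_points(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the simultaneous single-parameter fit."""

    dmu_cf2: float                    # J/mol
    std_error: float                  # J/mol, root of the estimator variance
    rmsd: float                       # pooled, N/m
    rmsd_per_surfactant: Mapping[str, float]   # N/m
    n_points: int
    converged: bool
    temperature: float
    betas: Mapping[int, float]
    excluded_surfactants: tuple[str, ...] = ()
    rt0: float = DEFAULT_CONSTANTS.rt0

    @property
    def dmu_cf2_rt0(self) -> float:
        """Fitted transfer energy in RT0 units."""
        return self.dmu_cf2 / self.rt0

    @property
    def std_error_rt0(self) -> float:
        return self.std_error / self.rt0


@dataclass(frozen=True)
class ThermoDecomposition:
    """Enthalpy/entropy split dmu(T) = dh - T*ds from linear regression."""

    enthalpy: float            # dh, J/mol
    entropy: float             # ds, J/(mol K)
    enthalpy_se: float
    entropy_se: float
    temperatures: tuple[float, ...]
    energies: tuple[float, ...]        # J/mol, inputs
    residuals: tuple[float, ...]       # J/mol, per temperature

    def predicted(self, temperature: float) -> float:
        return self.enthalpy - temperature * self.entropy


# ---------------------------------------------------------------------------
# forward model

def model_pressures(concentrations: Sequence[float], n: int, dmu_cf2: float,
                    temperature: float, beta: float,
                    constants: ModelConstants = DEFAULT_CONSTANTS,
                    cf3_ratio: float = 2.0,
                    include_length_term: bool = True) -> np.ndarray:
    """Surface pressures predicted by the full forward model, N/m.

    Chains the adsorption-constant model (-> Ka) with the sticky-disk
    isotherm and equation of state (-> Pi at each concentration).
    """
    ka = ka_model.adsorption_constant(n, dmu_cf2, temperature, constants,
                                      cf3_ratio, include_length_term)
    params = monolayer.MonolayerParams(
        area=constants.area_per_mole, beta=beta, ka=ka,
        temperature=temperature, gas_constant=constants.gas_constant)
    return np.array([
        monolayer.equilibrium_state(c, params).surface_pressure
        for c in concentrations])


def _beta_for(dataset: IsothermDataset,
              betas: Mapping[int, float] | None,
              constants: ModelConstants) -> float:
    if betas is not None and dataset.surfactant.n in betas:
        return betas[dataset.surfactant.n]
    return beta_parameter(dataset.surfactant.n, dataset.temperature,
                          constants).beta_total


# ---------------------------------------------------------------------------
# per-point estimator

def per_point_transfer_energy(concentration: float, pressure: float,
                              surfactant: Surfactant, temperature: float,
                              constants: ModelConstants = DEFAULT_CONSTANTS,
                              beta: float | None = None,
                              cf3_ratio: float = 2.0,
                              include_length_term: bool = True,
                              rtol: float = 1.0e-8) -> float:
    """Invert a single (C, Pi) measurement to a dmu_CF2 value, J/mol.

    Raises ``NoSolutionError`` when the implied Ka falls outside the range
    attainable for dmu_CF2 in [0.5, 4] RT0, and ``AmbiguityError`` if the
    residual is found to be non-monotone on the bracket (never silently
    picks a root).
    """
    if concentration <= 0:
        raise ValidityError(f"concentration must be positive, got {concentration}")
    if pressure <= 0:
        raise NoSolutionError(
            "Pi=0 leaves the adsorption constant indeterminate (Gamma=0)")
    if beta is None:
        beta = beta_parameter(surfactant.n, temperature, constants).beta_total
    params = monolayer.MonolayerParams(
        area=constants.area_per_mole, beta=beta, ka=1.0,  # ka unused by the EOS
        temperature=temperature, gas_constant=constants.gas_constant)
    gamma_ads = monolayer.invert_eos(pressure, params)
    fa = monolayer.activity_coefficient(gamma_ads, params)
    ka_obs = fa * gamma_ads / concentration

    lo, hi = (b * constants.rt0 for b in DMU_BRACKET_RT0)

    def residual(dmu: float) -> float:
        return ka_model.adsorption_constant(
            surfactant.n, dmu, temperature, constants, cf3_ratio,
            include_length_term) - ka_obs

    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise NoSolutionError(
            f"observed Ka={ka_obs:.4g} m outside the attainable range "
            f"[{r_lo + ka_obs:.4g}, {r_hi + ka_obs:.4g}] m for dmu_CF2 in "
            f"[{DMU_BRACKET_RT0[0]}, {DMU_BRACKET_RT0[1]}] RT0")
    # Ka(dmu) must be monotone on the bracket for the root to be unique.
    grid = np.linspace(lo, hi, 9)
    ka_grid = [residual(x) for x in grid]
    if np.any(np.diff(ka_grid) <= 0):
        raise AmbiguityError(
            "Ka(dmu_CF2) non-monotone on the search bracket; "
            "per-point inversion would be ambiguous")
    return brentq(residual, lo, hi, rtol=rtol, xtol=1e-12)


# ---------------------------------------------------------------------------
# simultaneous fit

def fit_transfer_energy(datasets: Sequence[IsothermDataset],
                        constants: ModelConstants = DEFAULT_CONSTANTS,
                        betas: Mapping[int, float] | None = None,
                        include_n1: bool = False,
                        initial_dmu: float | None = None,
                        cf3_ratio: float = 2.0,
                        include_length_term: bool = True) -> FitResult:
    """Fit one dmu_CF2 to all points of all datasets at one temperature.

    Minimises the sum of squared deviations between modelled and observed
    surface pressures with the Levenberg-Marquardt algorithm.  The
    standard error is the root of the estimator variance obtained from
    the Jacobian at the optimum with the residual variance estimated from
    the fit (dof = N - 1).

    n = 1 datasets are excluded (and reported in
    ``excluded_surfactants``) unless ``include_n1=True``.
    """
    if not datasets:
        raise ValidityError("no datasets supplied")
    temperatures = {d.temperature for d in datasets}
    if len(temperatures) != 1:
        raise ValidityError(
            f"all datasets must share one temperature, got {sorted(temperatures)}")
    temperature = temperatures.pop()

    excluded = tuple(d.surfactant.label for d in datasets
                     if d.surfactant.n == 1 and not include_n1)
    fit_sets = [d for d in datasets if include_n1 or d.surfactant.n != 1]
    n_points = sum(d.n_points for d in fit_sets)
    if n_points < 2:
        raise ValidityError("need at least 2 points after exclusions")

    beta_used = {d.surfactant.n: _beta_for(d, betas, constants)
                 for d in fit_sets}

    def residuals(x: np.ndarray) -> np.ndarray:
        dmu = float(x[0])
        out = []
        for d in fit_sets:
            model = model_pressures(d.concentrations, d.surfactant.n, dmu,
                                    temperature, beta_used[d.surfactant.n],
                                    constants, cf3_ratio, include_length_term)
            out.append(model - np.asarray(d.pressures))
        return np.concatenate(out)

    x0 = initial_dmu if initial_dmu is not None \
        else DMU_INITIAL_RT0 * constants.rt0
    sol = least_squares(residuals, x0=[x0], method="lm",
                        xtol=1e-12, ftol=1e-14, gtol=1e-14, max_nfev=400)
    if not sol.success:
        raise StickyDiskError(
            f"Levenberg-Marquardt fit did not converge: {sol.message}")
    dmu_hat = float(sol.x[0])
    lo, hi = (b * constants.rt0 for b in DMU_BRACKET_RT0)
    if not lo <= dmu_hat <= hi:
        raise StickyDiskError(
            f"optimum dmu_CF2={dmu_hat / constants.rt0:.3f} RT0 outside the "
            f"physically plausible range [{DMU_BRACKET_RT0[0]}, "
            f"{DMU_BRACKET_RT0[1]}] RT0")

    res = sol.fun
    jac = np.asarray(sol.jac)
    dof = max(n_points - 1, 1)
    s2 = float(res @ res) / dof
    jtj = float(np.squeeze(jac.T @ jac))
    std_error = math.sqrt(s2 / jtj) if jtj > 0 else math.inf

    rmsd_per: dict[str, float] = {}
    offset = 0
    for d in fit_sets:
        r = res[offset:offset + d.n_points]
        rmsd_per[d.surfactant.label] = float(np.sqrt(np.mean(r**2)))
        offset += d.n_points
    rmsd = float(np.sqrt(np.mean(res**2)))

    return FitResult(
        dmu_cf2=dmu_hat, std_error=std_error, rmsd=rmsd,
        rmsd_per_surfactant=rmsd_per, n_points=n_points, converged=True,
        temperature=temperature, betas=beta_used,
        excluded_surfactants=excluded, rt0=constants.rt0)


# ---------------------------------------------------------------------------
# enthalpy/entropy decomposition

def thermo_decomposition(
        energies: Sequence[tuple[float, float]]) -> ThermoDecomposition:
    """Split dmu_CF2(T) into dh and ds by ordinary least squares.

    ``energies`` is a sequence of (T in K, dmu_CF2 in J/mol) pairs at >= 2
    distinct temperatures.  The regression dmu = dh - T*ds treats both dh
    and ds as temperature independent; standard errors come from the
    regression covariance (undefined — NaN — for the exactly determined
    two-point case).
    """
    t = np.array([e[0] for e in energies], dtype=float)
    y = np.array([e[1] for e in energies], dtype=float)
    if len(np.unique(t)) < 2:
        raise ValidityError("need at least 2 distinct temperatures")
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = coef
    fitted = design @ coef
    resid = y - fitted
    dof = len(t) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        se_intercept = math.sqrt(cov[0, 0])
        se_slope = math.sqrt(cov[1, 1])
    else:
        se_intercept = se_slope = math.nan
    return ThermoDecomposition(
        enthalpy=float(intercept), entropy=float(-slope),
        enthalpy_se=se_intercept, entropy_se=se_slope,
        temperatures=tuple(t), energies=tuple(y),
        residuals=tuple(resid))


def energies_from_rt0_table(entries: Sequence[tuple[float, float]],
                            constants: ModelConstants = DEFAULT_CONSTANTS,
                            per_row_rt: bool = True) -> list[tuple[float, float]]:
    """Convert (T, dmu/RT0) table rows to absolute energies in J/mol.

    With ``per_row_rt=True`` (default) each row is scaled by R*T at its
    own temperature; with ``per_row_rt=False`` every row is scaled by the
    fixed R*T0.  The per-row convention is the one under which tabulated
    dimensionless energies and their published enthalpy/entropy split are
    mutually consistent; see the methods documentation.
    """
    out = []
    for temp, value in entries:
        scale = constants.gas_constant * (temp if per_row_rt
                                          else constants.reference_temperature)
        out.append((temp, value * scale))
    return out
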