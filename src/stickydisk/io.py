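"""CSV input/output, pipeline orchestration and reporting.

The on-disk isotherm format is one CSV with columns

    surfactant_label, n, temperature_K, concentration_mmol_per_L,
    surface_pressure_mN_per_m OR interfacial_tension_mN_per_m,
    [replicate_sd_mN_per_m]

Exactly one of the pressure/tension columns is present per file; tension
rows are converted via Pi = gamma0(T) - gamma with the neat-interface
correlation.  Concentration conversion mmol/L -> mol/m^3 is an exact
no-op (1 mmol/L = 1 mol/m^3) and is spelled out here so the unit
convention stays explicit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .constants import DEFAULT_CONSTANTS, ModelConstants, Surfactant
from .exceptions import ValidityError
from .inference import (FitResult, IsothermDataset, fit_transfer_energy,
                        thermo_decomposition)
from .synthetic import ExperimentDesign, generate_isotherms

logger = logging.getLogger(__name__)

PRESSURE_COL = "surface_pressure_mN_per_m"
TENSION_COL = "interfacial_tension_mN_per_m"
REQUIRED_COLS = ("surfactant_label", "n", "temperature_K",
                 "concentration_mmol_per_L")

#: Small negative pressures (rounding of gamma ~ gamma0) tolerated, N/m.
NEGATIVE_PI_TOLERANCE = 0.5e-3


def read_isotherms(path: str | Path,
                   constants: ModelConstants = DEFAULT_CONSTANTS
                   ) -> list[IsothermDataset]:
    """Read a CSV of isotherm points into per-(surfactant, T) datasets."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValidityError(f"{path}: missing required column(s) {missing}")
    has_pi = PRESSURE_COL in df.columns
    has_gamma = TENSION_COL in df.columns
    if has_pi == has_gamma:
        raise ValidityError(
            f"{path}: exactly one of '{PRESSURE_COL}' or '{TENSION_COL}' "
            "must be present")

    datasets: list[IsothermDataset] = []
    for (label, temp), group in df.groupby(["surfactant_label",
                                            "temperature_K"], sort=True):
        group = group.sort_values("concentration_mmol_per_L")
        n_values = group["n"].unique()
        if len(n_values) != 1:
            raise ValidityError(
                f"{path}: surfactant {label!r} has inconsistent n values "
                f"{sorted(n_values)}")
        gamma0 = constants.gamma0(float(temp))
        if has_pi:
            pi = group[PRESSURE_COL].to_numpy(dtype=float) * 1e-3
        else:
            pi = gamma0 - group[TENSION_COL].to_numpy(dtype=float) * 1e-3
        if (pi < -NEGATIVE_PI_TOLERANCE).any():
            bad = group.index[pi < -NEGATIVE_PI_TOLERANCE].tolist()
            raise ValidityError(
                f"{path}: rows {bad}: surface pressure below "
                f"-{NEGATIVE_PI_TOLERANCE * 1e3} mN/m")
        if (pi < 0).any():
            logger.warning("%s: clipped %d slightly negative pressure(s)",
                           path, int((pi < 0).sum()))
            pi = pi.clip(min=0.0)
        conc = group["concentration_mmol_per_L"].to_numpy(dtype=float)  # == mol/m^3
        datasets.append(IsothermDataset(
            surfactant=Surfactant(int(n_values[0]), str(label)),
            temperature=float(temp),
            concentrations=tuple(conc), pressures=tuple(pi),
            gamma0_used=gamma0, provenance=f"file: {path}"))
    return datasets


def write_isotherms(datasets: Sequence[IsothermDataset],
                    path: str | Path) -> None:
    """Write datasets to the CSV schema (pressure mode, mN/m and mmol/L)."""
    rows = []
    for d in datasets:
        for c, p in zip(d.concentrations, d.pressures):
            rows.append({
                "surfactant_label": d.surfactant.label,
                "n": d.surfactant.n,
                "temperature_K": d.temperature,
                "concentration_mmol_per_L": c,
                PRESSURE_COL: p * 1e3,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline

def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidityError(f"{path}: configuration must be a mapping")
    return cfg


def run_pipeline(config: Mapping[str, Any],
                 constants: ModelConstants = DEFAULT_CONSTANTS
                 ) -> dict[str, Any]:
    """Run the full analysis: attraction parameters, per-T fits, decomposition.

    ``config`` keys:

    * ``input`` — path to an isotherm CSV, or
    * ``simulate`` — a mapping with keys matching
      :class:`~stickydisk.synthetic.ExperimentDesign` plus
      ``true_dmu_cf2_rt0`` (scalar or per-temperature mapping);
    * ``include_n1`` (bool, default false) — include the n = 1 homologue;
    * ``betas`` — optional mapping n -> beta overriding the computed values.

    Returns a structured report: per-temperature fits (J/mol and RT0),
    standard errors, per-surfactant RMSD, the enthalpy/entropy split when
    more than one temperature is present, and every constant used.
    """
    if ("input" in config) == ("simulate" in config):
        raise ValidityError("config must name exactly one of 'input'/'simulate'")
    if "input" in config:
        datasets = read_isotherms(config["input"], constants)
    else:
        sim = dict(config["simulate"])
        dmu_cfg = sim.pop("true_dmu_cf2_rt0")
        if isinstance(dmu_cfg, Mapping):
            true_dmu = {float(t): float(v) * constants.rt0
                        for t, v in dmu_cfg.items()}
        else:
            true_dmu = float(dmu_cfg) * constants.rt0
        if "surfactants" in sim:
            sim["surfactants"] = tuple(Surfactant(int(n))
                                       for n in sim["surfactants"])
        for key in ("temperatures", "dilution_factors"):
            if key in sim:
                sim[key] = tuple(float(x) for x in sim[key])
        design = ExperimentDesign(**sim)
        datasets = generate_isotherms(design, true_dmu, constants)

    include_n1 = bool(config.get("include_n1", False))
    betas_cfg = config.get("betas")
    betas = ({int(k): float(v) for k, v in betas_cfg.items()}
             if betas_cfg else None)

    by_temperature: dict[float, list[IsothermDataset]] = {}
    for d in datasets:
        by_temperature.setdefault(d.temperature, []).append(d)

    fits: dict[float, FitResult] = {}
    for temp in sorted(by_temperature):
        fits[temp] = fit_transfer_energy(
            by_temperature[temp], constants, betas=betas,
            include_n1=include_n1)

    report: dict[str, Any] = {
        "constants": asdict(constants),
        "rt0_J_per_mol": constants.rt0,
        "include_n1": include_n1,
        "fits": {},
    }
    if include_n1:
        report["warning"] = ("n=1 homologue included on request; the "
                            "adsorption-constant model is known to be "
                            "inadequate for the first member of the series")
    for temp, fit in fits.items():
        report["fits"][temp] = {
            "dmu_cf2_J_per_mol": fit.dmu_cf2,
            "dmu_cf2_rt0": fit.dmu_cf2_rt0,
            "std_error_J_per_mol": fit.std_error,
            "std_error_rt0": fit.std_error_rt0,
            "rmsd_mN_per_m": fit.rmsd * 1e3,
            "rmsd_per_surfactant_mN_per_m": {
                k: v * 1e3 for k, v in fit.rmsd_per_surfactant.items()},
            "n_points": fit.n_points,
            "betas": dict(fit.betas),
            "excluded_surfactants": list(fit.excluded_surfactants),
        }
    if len(fits) >= 2:
        decomp = thermo_decomposition(
            [(t, f.dmu_cf2) for t, f in fits.items()])
        report["decomposition"] = {
            "enthalpy_kJ_per_mol": decomp.enthalpy / 1e3,
            "entropy_J_per_mol_K": decomp.entropy,
            "enthalpy_se_kJ_per_mol": decomp.enthalpy_se / 1e3,
            "entropy_se_J_per_mol_K": decomp.entropy_se,
            "residuals_J_per_mol": dict(zip(decomp.temperatures,
                                            decomp.residuals)),
        }
    return report


def format_report(report: Mapping[str, Any]) -> str:
    """Human-readable rendering of a pipeline report."""
    lines = ["Transfer-energy analysis report",
             "=" * 33]
    if "warning" in report:
        lines += [f"WARNING: {report['warning']}", ""]
    for temp, fit in report["fits"].items():
        lines.append(f"T = {temp} K:")
        lines.append(
            f"  dmu_CF2 = {fit['dmu_cf2_rt0']:.3f} +/- "
            f"{fit['std_error_rt0']:.3f} RT0 "
            f"({fit['dmu_cf2_J_per_mol']:.0f} +/- "
            f"{fit['std_error_J_per_mol']:.0f} J/mol)")
        lines.append(f"  pooled RMSD = {fit['rmsd_mN_per_m']:.3f} mN/m "
                     f"over {fit['n_points']} points")
        for label, rmsd in fit["rmsd_per_surfactant_mN_per_m"].items():
            lines.append(f"    {label}: RMSD {rmsd:.3f} mN/m")
        for n, beta in fit["betas"].items():
            lines.append(f"    beta(n={n}) = {beta:.4f}")
        if fit["excluded_surfactants"]:
            lines.append("  excluded: "
                         + ", ".join(fit["excluded_surfactants"]))
    if "decomposition" in report:
        d = report["decomposition"]
        lines.append("Enthalpy/entropy decomposition:")
        lines.append(f"  dh = {d['enthalpy_kJ_per_mol']:.2f} kJ/mol, "
                     f"ds = {d['entropy_J_per_mol_K']:.2f} J/(mol K)")
    return "\n".join(lines)


def report_fits_to_frame(report: Mapping[str, Any]) -> pd.DataFrame:
    """Machine-readable (CSV-ready) table of the per-temperature fits."""
    rows = []
    for temp, fit in report["fits"].items():
        rows.append({
            "temperature_K": temp,
            "dmu_cf2_J_per_mol": fit["dmu_cf2_J_per_mol"],
            "dmu_cf2_rt0": fit["dmu_cf2_rt0"],
            "std_error_J_per_mol": fit["std_error_J_per_mol"],
            "std_error_rt0": fit["std_error_rt0"],
            "rmsd_mN_per_m": fit["rmsd_mN_per_m"],
            "n_points": fit["n_points"],
        })
    return pd.DataFrame(rows)
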