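"""Recover the transfer energy from a noisy synthetic campaign.

Generates one synthetic tensiometry experiment at 293.15 K (homologues
n = 2 and 3, three concentrations each, pressure noise 0.26 mN/m), then
estimates dmu_CF2 two ways: point by point, and by the simultaneous
single-parameter least-squares fit.
"""

from stickydisk import (DEFAULT_CONSTANTS, ExperimentDesign,
                        fit_transfer_energy, generate_isotherms,
                        per_point_transfer_energy)

constants = DEFAULT_CONSTANTS
true_dmu = 1.75 * constants.rt0

datasets = generate_isotherms(ExperimentDesign(seed=42), true_dmu)
print("Per-point inversions (Pi -> Gamma -> fa -> Ka -> dmu_CF2):")
for d in datasets:
    for c, p in zip(d.concentrations, d.pressures):
        dmu = per_point_transfer_energy(c, p, d.surfactant, d.temperature)
        print(f"  {d.surfactant.label:>16}  C={c:7.2f} mM  "
              f"Pi={p * 1e3:5.2f} mN/m  ->  {dmu / constants.rt0:.3f} RT0")

fit = fit_transfer_energy(datasets)
print(f"\nSimultaneous fit over {fit.n_points} points:")
print(f"  dmu_CF2 = {fit.dmu_cf2_rt0:.3f} +/- {fit.std_error_rt0:.3f} RT0 "
      f"(injected truth: 1.750)")
print(f"  pooled RMSD = {fit.rmsd * 1e3:.3f} mN/m "
      f"(noise SD was 0.26 mN/m)")
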