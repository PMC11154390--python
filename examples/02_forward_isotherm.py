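"""Forward model: from a transfer energy to a pressure isotherm.

Given the -CF2- transfer energy, the model predicts the adsorption
constant Ka of each homologue (adsorption length x Boltzmann factor of
the adsorption energy, with the short-chain Traube correction) and, via
the sticky-disk equation of state, the surface pressure at any bulk
concentration.
"""

import numpy as np

from stickydisk import (DEFAULT_CONSTANTS, adsorption_energetics,
                        beta_parameter, model_pressures)

constants = DEFAULT_CONSTANTS
temperature = 293.15
dmu = 1.75 * constants.rt0   # J/mol

for n in (2, 3):
    e = adsorption_energetics(n, dmu, temperature)
    beta = beta_parameter(n, temperature).beta_total
    print(f"n={n}: delta_a = {e.adsorption_length * 1e10:.3f} A, "
          f"Ea = {e.adsorption_energy / 1e3:.2f} kJ/mol, "
          f"Ka = {e.adsorption_constant * 1e6:.3f} um")
    concentrations = np.array([2.0, 8.0, 32.0]) / (4 ** (n - 2))  # mol/m^3
    pressures = model_pressures(concentrations, n, dmu, temperature, beta)
    for c, p in zip(concentrations, pressures):
        print(f"   C = {c:6.2f} mM  ->  Pi = {p * 1e3:5.2f} mN/m")

print()
print("Each added CF2 group raises surface activity ~5-6x (Traube's rule),")
print("so the longer homologue reaches the same pressure at ~5x lower C.")
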