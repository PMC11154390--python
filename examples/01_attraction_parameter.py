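"""Lateral cohesion of the fluorocarbon monolayer.

Computes the sticky-disk attraction parameter beta for the three shortest
fluorotelomer alcohols at 293 K.  beta is the sum of a solvent-depletion
(osmotic) term and a dispersion term from the London attraction between
upright perfluorinated tails through hexane; it grows with tail length
and shrinks with temperature.
"""

from stickydisk import beta_parameter

for n in (1, 2, 3):
    bd = beta_parameter(n, 293.0)
    print(f"n={n}: beta = {bd.beta_total:.4f} "
          f"(osmotic {bd.beta_osmotic:.2f} + dispersion "
          f"{bd.beta_dispersion:.4f}) -> tabulated as {bd.beta_total:.2f}")

print()
print("Temperature dependence for n=3 (Boltzmann weighting weakens with T):")
for temperature in (288.15, 293.15, 303.15):
    bd = beta_parameter(3, temperature)
    print(f"  T={temperature} K: beta = {bd.beta_total:.4f}")
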