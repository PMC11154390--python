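# stickydisk

Thermodynamic analysis of short fluorotelomer alcohols
(F(CF₂)ₙCH₂OH, n = 1–3) adsorbing from water onto the water|hexane
interface, built to determine the **free energy of transfer of a –CF₂–
moiety from oil to water**, Δμ_CF2 — the parameter that controls, through
exponential Traube-rule scaling, the adsorption constants and partition
coefficients of water-soluble perfluoroalkyl (PFAS-class) surfactants.
Literature values for Δμ_CF2 disagree by more than ±25%, which propagates
to order-of-magnitude errors in predicted environmental partitioning; an
accurate tensiometric determination narrows that down.

The package is a library first: import it, or start from the short
narrative scripts in `examples/`. A thin `stickydisk` CLI wraps the same
functions for shell pipelines.

## The model

**Sticky-disk (SD) monolayer.** Adsorbed surfactants are hard disks of
molar parking area α (24.5 Å²/molecule, set by the helical fluorocarbon
cross-section) moving freely on the interface, with a one-dimensional
sticky attraction of strength β. The equation of state and the associated
surface activity coefficient are

    Π = RT (R_β − 1) / (2αβ(1 − αΓ)),   R_β = √(1 + 4βαΓ/(1 − αΓ)),

    f_a = [1/(1−αΓ)] · [2/(1+R_β)]^(2+1/β)
          · exp[ αΓ(4−3αΓ)/(1−αΓ)² · 2/(1+R_β) ],

where Γ is the adsorption (mol/m²) and Π = γ₀ − γ the surface pressure.
The pair is Gibbs-consistent and reduces to the scaled-particle hard-disk
EOS as β → 0. β itself is predicted, not fitted: an osmotic term
(β_osm = 0.17) plus a quadrature of the London attraction between
n-segment fluorocarbon tails through hexane, giving β = 0.26, 0.51, 0.94
for n = 1, 2, 3 at 293 K.

**Adsorption constant.** The isotherm is K_a·C = f_a·Γ with

    K_a = δ_a (1 − e^(−nΔμ_CF2/RT)) e^(−E_a/RT) − n·l_CF2,
    δ_a = RT·l_CF2 / (2Δμ_CF2),
    E_a = −(2√3/π)·α·γ₀(T) − (n+1)·Δμ_CF2,

with Δμ_CF3 = 2Δμ_CF2 folded into the (n+1) chain term. The explicit
(1 − e^(−nΔμ/RT)) factor corrects Traube's rule for very short chains —
the key to using n = 2, 3 homologues quantitatively. This leaves a single
unknown, Δμ_CF2, estimated by simultaneous Levenberg–Marquardt fitting of
all pressure points at one temperature, then decomposed across
temperatures as Δμ_CF2(T) = Δh − TΔs.

Raw isotherms for this system are not numerically published, so a
synthetic tensiometry generator (`stickydisk.synthetic`) reproduces the
experiment's design — three concentrations per homologue (top, /2, /4),
Gaussian pressure noise of SD 0.26 mN/m, optional ≤3% co-adsorbing
impurity — making every inference stage testable end to end.

## Worked example

```python
import numpy as np
from stickydisk import (DEFAULT_CONSTANTS, ExperimentDesign,
                        fit_transfer_energy, generate_isotherms)

constants = DEFAULT_CONSTANTS
true_dmu = 1.75 * constants.rt0          # inject 1.75 RT0 ~ 4338 J/mol
datasets = generate_isotherms(ExperimentDesign(seed=42), true_dmu)
fit = fit_transfer_energy(datasets)
print(f"dmu_CF2 = {fit.dmu_cf2_rt0:.3f} +/- {fit.std_error_rt0:.3f} RT0")
print(f"pooled RMSD = {fit.rmsd * 1e3:.3f} mN/m")
```

prints

```
dmu_CF2 = 1.742 +/- 0.007 RT0
pooled RMSD = 0.270 mN/m
```

i.e. from one noisy six-point campaign (two homologues × three
concentrations at 293.15 K) the single-parameter fit recovers the
injected transfer energy to about one standard error, and the residual
scatter (0.27 mN/m) matches the 0.26 mN/m measurement noise. The same
workflow from the shell:

```sh
stickydisk simulate --out iso.csv --seed 42 --dmu-cf2 1.75
stickydisk fit --input iso.csv
stickydisk beta --n 3 --temperature 293
```

See `examples/` for the attraction-parameter breakdown, the forward
isotherm model, per-point inversion, the three-temperature
enthalpy/entropy pipeline and a 200-replicate Monte-Carlo recovery study.

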