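# Methods

## Scope and physical picture

The package estimates the free energy Δμ_CF2 of transferring one –CF₂–
group from a hydrophobic (hexane) phase into water, from equilibrium
interfacial-tension isotherms of the homologous nonionic surfactants
F(CF₂)ₙCH₂OH at the water|hexane interface. Only the shortest homologues
(n ≤ 3) are water-soluble, and short chains deviate from Traube's rule,
so the analysis couples two models:

1. a **sticky-disk (SD) monolayer** equation of state relating surface
   pressure Π, adsorption Γ and bulk concentration C, and
2. a **molecular-thermodynamic adsorption-constant model** that makes the
   short-chain deviation explicit, leaving Δμ_CF2 as the only unknown.

All internal quantities are SI (J, m, mol, K, N/m). The user-facing
units are mN/m for pressures/tensions, mmol/L for concentrations (an
exact alias of mol/m³), and the dimensionless RT₀ energy unit
(R·298.15 K ≈ 2.479 kJ/mol) for transfer energies.

## The sticky-disk pair and its limits

The EOS and activity coefficient (see README for the formulas) are a
thermodynamically consistent pair: the Gibbs adsorption equation
dΠ/dΓ = RT·Γ·d ln(f_a Γ)/dΓ holds, which the test suite verifies by
central differences on a grid η = αΓ ∈ [0.05, 0.8], β ∈ [0, 2] to a
relative tolerance of 10⁻⁵. Two analytic limits anchor the
implementation:

* β → 0 reduces to the scaled-particle hard-disk EOS
  Π = RTΓ/(1−η)² with ln f_a = −ln(1−η) − η/(1−η) + η(4−3η)/(1−η)².
  Because (R_β−1)/β and the (2+1/β) exponent are 0/0 at β = 0, the code
  switches to these closed forms below β = 10⁻⁶; continuity across the
  switch is tested.
* Γ → 0 recovers the two-dimensional ideal-gas law Π = RTΓ for all β.

Numerical inversions (Π → Γ, and the isotherm K_a C = f_a Γ → Γ) use
bracketed Brent root finding on the coverage η ∈ [0, 1−10⁻⁶]. The
isotherm solve works in log space because f_a overflows a double well
before close packing; below coverage 10⁻¹⁸ the Henry limit Γ = K_a C is
returned directly. The hard-disk EOS diverges towards η → 1, so
"unattainable pressure" is only meaningful against a caller-imposed
coverage ceiling; in the pipeline the dataset invariant 0 ≤ Π < γ₀
bounds all inputs before inversion.

The model is restricted to weakly cohesive monolayers: parameters with
β ≥ 38 are rejected outright, and monotonicity of Π(Γ) and Γ(C) — which
uniqueness of every inversion relies on — is asserted and tested for
β ≤ 2, comfortably covering the study range β ≤ 0.95.

## Attraction parameter

β = β_osm + β_disp(n, T). The osmotic (solvent-depletion) term is the
constant 0.17 established for perfluoroalkylated alcohols at
water|hexane. The dispersion term integrates the Boltzmann excess of the
pair attraction u(r) between two upright n-segment tails,

    β_disp = (1/R²_CF2) ∫_{2R_CF2}^∞ [e^{u(r)} − 1] r dr,
    u(r) = nL_CF2/(4RT·l_CF2·r⁵) · [ n·l_CF2·r/(r²+n²l²_CF2)
                                     + 3·arctan(n·l_CF2/r) ],

with l_CF2 = 1.306 Å the segment height, R_CF2 = √(α_CF2/π) = 2.79 Å the
segment radius and L_CF2 = 6.32×10⁻⁵⁴ J·m⁶/mol the effective
segment–segment London constant through hexane. u(r) is non-negative and
decays as the point-pair London law r⁻⁶ for r ≫ n·l_CF2 (both tested).
The infinite integral is mapped onto u ∈ (0, 1] by r = 2R_CF2/u and
evaluated by adaptive quadrature to an absolute accuracy of 10⁻⁶ on β —
without the mapping, generic quadrature misses the sub-nanometre feature
entirely. The three two-decimal anchors β(1, 2, 3; 293 K) =
0.26, 0.51, 0.94 are regression-tested; they also fix the transcription
of u(r), whose typography admits variants (e.g. a spurious factor 5 on
the first bracket term triples β_disp and breaks all three anchors).
Temperature dependence enters only through the Boltzmann factor; the
parking area is held at its 24.5 Ų helical value at all temperatures,
with the 21.6 Ų antiperiplanar alternative available as a sensitivity
setting (~5% effect on the transfer energy).

## Adsorption-constant model

K_a(n) = δ_a(1 − e^{−nΔμ_CF2/RT})·e^{−E_a/RT} − n·l_CF2, with
δ_a = RT·l_CF2/(2Δμ_CF2) and
E_a = −(2√3/π)α·γ₀(T) − (n+1)Δμ_CF2. Design choices:

* The packing coefficient is 2√3/π ≈ 1.1027 — the area of the
  quasi-hexagonal cell per molecule over the hard-disk area — multiplying
  the interfacial work term α·γ₀.
* γ₀(T) is the neat water|hexane tension at the dataset temperature,
  from the linear correlation γ₀/[mN/m] = 50.56 − 0.0876·(T/K − 298.15).
* Δμ_CF3 = 2·Δμ_CF2 by the contact-area argument; the ratio is exposed
  (`cf3_ratio`) but not fitted.
* The trailing −n·l_CF2 length correction is below 1% of K_a for every
  study condition (tested); it is on by default and switchable
  (`include_length_term=False`), so either reading of its placement
  leaves results unchanged at the reported precision.
* For n ≥ 8 the suppression factor is ~1 and K_a collapses to the Davies
  form δ_a·e^{−E_a/RT}; the Traube factor K_a(n+1)/K_a(n) = e^{Δμ/RT}
  then lies in [5, 6] for Δμ_CF2 ≈ 1.75 RT₀ (tested).
* K_a(Δμ) is strictly increasing on Δμ ∈ [0.5, 4] RT₀ for n = 2, 3
  (tested), which guarantees a unique per-point inversion.

## Estimators

**Per-point.** Each (C, Π) measurement is chained through
Γ = EOS⁻¹(Π), f_a(Γ), K_a = f_a Γ/C, and Δμ_CF2 = K_a⁻¹ on the bracket
[0.5, 4] RT₀ (Brent, relative tolerance 10⁻⁸). Monotonicity of K_a(Δμ)
is re-checked on the bracket at run time; a non-monotone residual raises
rather than silently picking a root. Π = 0 is rejected (K_a
indeterminate).

**Simultaneous fit.** One Δμ_CF2 per temperature minimises
Σ(Π_model − Π_obs)² over all points of all homologues at that
temperature (unweighted, matching plain RMS minimisation), via
Levenberg–Marquardt (scipy `least_squares(method="lm")`, initial value
1.7 RT₀, parameter/function tolerances 10⁻¹²/10⁻¹⁴); an optimum outside
[0.5, 4] RT₀ is reported as an error rather than returned. The standard
error is the root of the estimator variance, s²/(JᵀJ) with
s² = RSS/(N−1) and J the Jacobian at the optimum. Per-homologue and
pooled RMSDs are reported. The n = 1 homologue is excluded by default —
the K_a model is inadequate for the first member of the series, whose
polar-leaning CF₃ terminus likely flattens the adsorbed orientation —
and any excluded dataset is named in the result; `include_n1=True`
overrides, with a prominent warning in pipeline reports.

**Decomposition.** Δμ_CF2(T) = Δh − TΔs by ordinary least squares over
the per-temperature fits; slope = −Δs, intercept = Δh, standard errors
from the regression covariance (NaN for the exactly determined two-point
case). A note on units: tabulated *dimensionless* transfer energies are
conventionally quoted in RT₀ units, but a decomposition of such a table
only reproduces the matching published Δh ≈ −10.0 kJ/mol and
Δs ≈ −48.7 J/(mol·K) when each row is converted to J/mol with R·T at its
own temperature, not with the fixed R·T₀ (which yields ≈ −5.3 kJ/mol and
−32.9 J/(mol·K)). `energies_from_rt0_table` therefore defaults to
per-row R·T scaling and documents both conventions; which unrounded
values stand behind any given published split cannot be reconstructed
from a rounded table, so both paths are kept explicit rather than
silently merged.

## Synthetic tensiometry

The generator emulates the information content of the real experiment
rather than copying unpublished numbers:

* **Design.** Homologues n = 2 and 3 (n = 1 available), temperatures
  from {288.15, 293.15, 303.15} K, three concentrations per homologue:
  the top anchored where the forward model predicts 15 mN/m — standing
  in for "near the solubility limit", since solubilities are not
  tabulated — then twofold and fourfold dilutions. With this anchor the
  six pressures per temperature span roughly 7–15 mN/m, the upper
  portion of the measured 2–15 mN/m window.
* **Noise.** Independent, homoscedastic Gaussian with SD 0.26 mN/m (the
  tensiometer repeatability, the only published error model), clipped at
  Π = 0 with clipping logged. The empirical SD over >10⁴ draws is tested
  to 3%.
* **Impurity (optional, beyond-measurement).** A second nonionic species
  of chain n + 1 at mole fraction ≤ 3% co-adsorbs in a mixed SD
  monolayer with shared α and β, each species obeying
  K_a,i·C_i = f_a(η_tot)·Γ_i — the simplest thermodynamically consistent
  extension. It is used only for directional robustness checks
  (contamination biases Π upward and inflates fit RMSD), never in
  acceptance quantities.

What the generator does **not** emulate: adsorption kinetics and the
~6 h equilibration, drop-shape (Young–Laplace) image analysis, bulk
depletion, surfactant partitioning into the oil drop, temperature drift,
or any heteroscedasticity of real tensiometry. Passing recovery tests
therefore demonstrates that the estimator chain is correct and unbiased
under the stated error model — not that real measurements are free of
systematic effects.

## Problem sizes and numerical defaults

Monte-Carlo studies use 200 replicates of the six-point study design;
at that size the recovered mean is reproducible to ±0.01 RT₀ across
seeds. Noise- and sample-size-scaling checks of the standard error use
200 replicates per condition. Quadrature tolerance on β is 10⁻⁶
absolute; EOS inversions are converged to 10⁻¹⁰ relative or better;
isotherm solves to near machine precision. Randomness flows exclusively
through `numpy.random.Generator` objects seeded at the entry points.

## Known limitations

* The model chain is single-component and nonionic; no electrostatics.
* β ≥ 38 (condensed, strongly cohesive monolayers) is outside validity
  and rejected; monotonicity guarantees are only asserted for β ≤ 2.
* The temperature dependence of the parking area is neglected; the
  experimentally observed β(T) is known to be somewhat steeper than the
  osmotic+dispersion prediction, and no empirical correction is applied
  (a per-dataset β override is available instead).
* The n = 1 homologue is modelled but flagged: its inferred transfer
  energies sit far above the n ≥ 2 cluster, and the adsorption-length
  factor ½ would need re-derivation for a horizontally adsorbed
  molecule. Conclusions should rest on n ≥ 2.
* An entropy near −49 J/(mol·K) per –CF₂– is several times larger than
  the hydrocarbon analogue scaled by contact area; part of it may be an
  artefact of the temperature-independent α assumption. The fitted
  Δμ_CF2 values themselves move by under 5% across that assumption's
  plausible range.
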