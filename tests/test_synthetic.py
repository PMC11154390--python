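"""Synthetic tensiometry generator: determinism, noise model, impurity."""

import numpy as np
import pytest

from stickydisk import (DesignError, ExperimentDesign, Surfactant,
                        choose_top_concentration, fit_transfer_energy,
                        generate_isotherms, mixed_monolayer_pressures,
                        model_pressures)
from stickydisk.cohesion import beta_parameter


class TestDesign:
    def test_defaults_match_study_conditions(self):
        d = ExperimentDesign()
        assert tuple(s.n for s in d.surfactants) == (2, 3)
        assert d.dilution_factors == (1.0, 2.0, 4.0)
        assert d.noise_sd == pytest.approx(0.26e-3)
        assert d.impurity_fraction == 0.0

    def test_invalid_designs_rejected(self):
        with pytest.raises(DesignError):
            ExperimentDesign(dilution_factors=(2.0, 4.0))
        with pytest.raises(DesignError):
            ExperimentDesign(noise_sd=-1.0)
        with pytest.raises(DesignError):
            ExperimentDesign(impurity_fraction=0.1)


class TestTopConcentration:
    def test_zero_target(self, constants, rt0):
        assert choose_top_concentration(Surfactant(2), 293.15, 0.0,
                                        1.75 * rt0, constants) == 0.0

    def test_forward_model_round_trip(self, constants, rt0, study_betas):
        for n in (2, 3):
            c = choose_top_concentration(Surfactant(n), 293.15, 15e-3,
                                         1.75 * rt0, constants,
                                         beta=study_betas[n])
            pi = model_pressures([c], n, 1.75 * rt0, 293.15,
                                 study_betas[n], constants)[0]
            assert pi == pytest.approx(15e-3, rel=1e-8)

    def test_longer_homologue_needs_less(self, constants, rt0):
        c2 = choose_top_concentration(Surfactant(2), 293.15, 10e-3,
                                      1.75 * rt0, constants)
        c3 = choose_top_concentration(Surfactant(3), 293.15, 10e-3,
                                      1.75 * rt0, constants)
        # surface activity grows roughly by the Traube factor per CF2
        assert 3.0 < c2 / c3 < 9.0

    def test_unattainable_target(self, constants, rt0):
        with pytest.raises(DesignError):
            choose_top_concentration(Surfactant(2), 293.15, 60e-3,
                                     1.75 * rt0, constants)


class TestGenerator:
    def test_noiseless_equals_forward_model(self, constants, rt0,
                                            study_betas):
        datasets = generate_isotherms(
            ExperimentDesign(noise_sd=0.0, seed=1), 1.75 * rt0, constants)
        for d in datasets:
            expected = model_pressures(d.concentrations, d.surfactant.n,
                                       1.75 * rt0, 293.15,
                                       study_betas[d.surfactant.n], constants)
            assert np.allclose(d.pressures, expected, rtol=1e-10)

    def test_seed_determinism(self, constants, rt0):
        a = generate_isotherms(ExperimentDesign(seed=11), 1.75 * rt0,
                               constants)
        b = generate_isotherms(ExperimentDesign(seed=11), 1.75 * rt0,
                               constants)
        c = generate_isotherms(ExperimentDesign(seed=12), 1.75 * rt0,
                               constants)
        for da, db in zip(a, b):
            assert da.pressures == db.pressures
        assert any(da.pressures != dc.pressures for da, dc in zip(a, c))

    def test_empirical_noise_sd(self, constants, rt0):
        """Pooled SD of generated noise matches the nominal 0.26 mN/m."""
        design = ExperimentDesign()
        clean = {(d.surfactant.n,): np.asarray(d.pressures)
                 for d in generate_isotherms(
                     ExperimentDesign(noise_sd=0.0, seed=0), 1.75 * rt0,
                     constants)}
        rng = np.random.default_rng(123)
        residuals = []
        for _ in range(1800):
            for d in generate_isotherms(design, 1.75 * rt0, constants,
                                        rng=rng):
                residuals.append(np.asarray(d.pressures)
                                 - clean[(d.surfactant.n,)])
        sd = np.std(np.concatenate(residuals))
        assert sd == pytest.approx(design.noise_sd, rel=0.03)

    def test_generated_datasets_satisfy_invariants(self, constants, rt0):
        rng = np.random.default_rng(5)
        for _ in range(50):
            for d in generate_isotherms(ExperimentDesign(), 1.75 * rt0,
                                        constants, rng=rng):
                assert np.all(np.diff(d.concentrations) > 0)
                assert all(0 <= p < d.gamma0_used for p in d.pressures)

    def test_per_temperature_energy_mapping(self, constants, rt0):
        datasets = generate_isotherms(
            ExperimentDesign(temperatures=(288.15, 303.15), noise_sd=0.0,
                             seed=0),
            {288.15: 1.68 * rt0, 303.15: 1.88 * rt0}, constants)
        temps = {d.temperature for d in datasets}
        assert temps == {288.15, 303.15}
        with pytest.raises(DesignError):
            generate_isotherms(
                ExperimentDesign(temperatures=(293.15,), seed=0),
                {288.15: 1.68 * rt0}, constants)


class TestImpurity:
    def test_zero_fraction_identity(self, constants, rt0, study_betas):
        conc = [5.0, 10.0, 20.0]
        pure = model_pressures(conc, 2, 1.75 * rt0, 293.15, study_betas[2],
                               constants)
        mixed = mixed_monolayer_pressures(conc, 2, 3, 0.0, 1.75 * rt0,
                                          293.15, study_betas[2], constants)
        assert np.allclose(pure, mixed, rtol=1e-12)

    def test_bias_positive_and_larger_for_shorter_homologue(
            self, constants, rt0, study_betas):
        """A given surface-active contaminant raises Pi, and the bias is
        larger for the less surface-active (shorter) main component, whose
        adsorption constant it exceeds by a larger Traube factor."""
        dmu = 1.75 * rt0
        n_impurity = 4  # one shared contaminant species for both mains
        biases = {}
        for n in (2, 3):
            conc = [choose_top_concentration(Surfactant(n), 293.15, 10e-3,
                                             dmu, constants,
                                             beta=study_betas[n])]
            pure = model_pressures(conc, n, dmu, 293.15, study_betas[n],
                                   constants)
            mixed = mixed_monolayer_pressures(conc, n, n_impurity, 0.03, dmu,
                                              293.15, study_betas[n],
                                              constants)
            biases[n] = float(mixed[0] - pure[0])
        assert biases[2] > 0 and biases[3] > 0
        assert biases[2] > biases[3]

    def test_contamination_raises_fit_rmsd(self, constants, rt0):
        """Fitting contaminated data with the pure model degrades the fit."""
        dmu = 1.75 * rt0
        rng_clean = np.random.default_rng(21)
        rng_dirty = np.random.default_rng(21)
        rmsd_clean, rmsd_dirty = [], []
        for _ in range(20):
            clean = generate_isotherms(ExperimentDesign(), dmu, constants,
                                       rng=rng_clean)
            dirty = generate_isotherms(
                ExperimentDesign(impurity_fraction=0.03), dmu, constants,
                rng=rng_dirty)
            rmsd_clean.append(fit_transfer_energy(clean, constants).rmsd)
            rmsd_dirty.append(fit_transfer_energy(dirty, constants).rmsd)
        assert np.mean(rmsd_dirty) > np.mean(rmsd_clean)
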