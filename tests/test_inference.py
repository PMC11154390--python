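"""Transfer-energy estimators: round trips, recovery, decomposition."""

import numpy as np
import pytest

from stickydisk import (ExperimentDesign, IsothermDataset, NoSolutionError,
                        Surfactant, ValidityError, energies_from_rt0_table,
                        fit_transfer_energy, generate_isotherms,
                        model_pressures, per_point_transfer_energy,
                        thermo_decomposition)


def make_dataset(n, dmu, temperature, concentrations, constants, beta):
    pis = model_pressures(concentrations, n, dmu, temperature, beta, constants)
    return IsothermDataset(
        surfactant=Surfactant(n), temperature=temperature,
        concentrations=tuple(concentrations), pressures=tuple(pis),
        gamma0_used=constants.gamma0(temperature))


class TestPerPoint:
    @pytest.mark.parametrize("n, conc", [(2, 8.0), (2, 40.0), (3, 1.0), (3, 10.0)])
    def test_forward_inverse_round_trip(self, constants, rt0, study_betas,
                                        n, conc):
        dmu_true = 1.75 * rt0
        pi = model_pressures([conc], n, dmu_true, 293.15, study_betas[n],
                             constants)[0]
        recovered = per_point_transfer_energy(
            conc, pi, Surfactant(n), 293.15, constants, beta=study_betas[n])
        assert recovered == pytest.approx(dmu_true, rel=1e-6)

    def test_zero_pressure_degenerate(self, constants):
        with pytest.raises(NoSolutionError):
            per_point_transfer_energy(1.0, 0.0, Surfactant(2), 293.15,
                                      constants)

    def test_unattainable_ka_reports_range(self, constants, study_betas):
        # an absurdly dilute solution at high pressure implies Ka beyond
        # anything reachable for dmu in [0.5, 4] RT0
        with pytest.raises(NoSolutionError, match="attainable"):
            per_point_transfer_energy(1e-12, 10e-3, Surfactant(2), 293.15,
                                      constants, beta=study_betas[2])


class TestSimultaneousFit:
    def test_noiseless_exact_recovery(self, constants, rt0, study_betas):
        dmu_true = 1.75 * rt0
        datasets = [
            make_dataset(2, dmu_true, 293.15, (10.0, 20.0, 40.0), constants,
                         study_betas[2]),
            make_dataset(3, dmu_true, 293.15, (2.0, 4.0, 8.0), constants,
                         study_betas[3]),
        ]
        fit = fit_transfer_energy(datasets, constants,
                                  betas={2: study_betas[2], 3: study_betas[3]})
        assert fit.dmu_cf2 == pytest.approx(dmu_true, rel=1e-8)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert fit.converged
        assert fit.n_points == 6

    def test_per_point_agrees_with_global_fit_on_clean_data(
            self, constants, rt0, study_betas):
        dmu_true = 1.68 * rt0
        datasets = [
            make_dataset(2, dmu_true, 288.15, (10.0, 20.0, 40.0), constants,
                         study_betas[2]),
        ]
        fit = fit_transfer_energy(datasets, constants,
                                  betas={2: study_betas[2]})
        for c, p in zip(datasets[0].concentrations, datasets[0].pressures):
            point = per_point_transfer_energy(c, p, Surfactant(2), 288.15,
                                              constants, beta=study_betas[2])
            assert point == pytest.approx(fit.dmu_cf2, rel=1e-6)

    def test_n1_excluded_by_default(self, constants, rt0, study_betas):
        dmu_true = 1.75 * rt0
        # n=1 dataset deliberately generated with a very different energy:
        # it must not pull the fit away from the n>=2 value
        datasets = [
            make_dataset(1, 2.15 * rt0, 293.15, (100.0, 200.0, 400.0),
                         constants, study_betas[1]),
            make_dataset(2, dmu_true, 293.15, (10.0, 20.0, 40.0), constants,
                         study_betas[2]),
            make_dataset(3, dmu_true, 293.15, (2.0, 4.0, 8.0), constants,
                         study_betas[3]),
        ]
        fit = fit_transfer_energy(datasets, constants)
        assert fit.excluded_surfactants == ("CF3CH2OH",)
        assert fit.dmu_cf2 == pytest.approx(dmu_true, rel=1e-8)
        assert fit.n_points == 6

    def test_include_n1_override_changes_result(self, constants, rt0,
                                                study_betas):
        datasets = [
            make_dataset(1, 2.15 * rt0, 293.15, (100.0, 200.0), constants,
                         study_betas[1]),
            make_dataset(2, 1.75 * rt0, 293.15, (10.0, 20.0), constants,
                         study_betas[2]),
        ]
        default = fit_transfer_energy(datasets, constants)
        forced = fit_transfer_energy(datasets, constants, include_n1=True)
        assert not forced.excluded_surfactants
        assert forced.dmu_cf2 > default.dmu_cf2

    def test_mixed_temperatures_rejected(self, constants, rt0, study_betas):
        datasets = [
            make_dataset(2, 1.75 * rt0, 293.15, (10.0, 20.0), constants,
                         study_betas[2]),
            make_dataset(3, 1.75 * rt0, 303.15, (2.0, 4.0), constants,
                         study_betas[3]),
        ]
        with pytest.raises(ValidityError, match="temperature"):
            fit_transfer_energy(datasets, constants)

    def test_estimator_consistency_noise_to_zero(self, constants, rt0):
        """Bias of the fit shrinks as the noise SD is reduced tenfold."""
        dmu_true = 1.75 * rt0
        biases = []
        for sd in (0.26e-3, 0.026e-3, 0.0026e-3):
            rng = np.random.default_rng(7)
            recovered = []
            for _ in range(20):
                datasets = generate_isotherms(
                    ExperimentDesign(noise_sd=sd), dmu_true, constants,
                    rng=rng)
                recovered.append(fit_transfer_energy(datasets,
                                                     constants).dmu_cf2)
            biases.append(abs(np.mean(recovered) - dmu_true))
        assert biases[2] < biases[0]
        assert biases[2] / rt0 < 1e-3


class TestThermoDecomposition:
    def test_exact_line(self):
        # dmu(T) = 5000 - T*(-40): dh = 5000 J/mol, ds = -40 J/(mol K)
        pairs = [(t, 5000.0 + 40.0 * t) for t in (288.15, 293.15, 303.15)]
        d = thermo_decomposition(pairs)
        assert d.enthalpy == pytest.approx(5000.0, abs=1e-6)
        assert d.entropy == pytest.approx(-40.0, abs=1e-9)
        assert np.allclose(d.residuals, 0.0, atol=1e-9)

    def test_two_point_exact_interpolation(self):
        pairs = [(290.0, 4000.0), (300.0, 4500.0)]
        d = thermo_decomposition(pairs)
        assert d.predicted(290.0) == pytest.approx(4000.0, abs=1e-8)
        assert d.predicted(300.0) == pytest.approx(4500.0, abs=1e-8)
        assert np.isnan(d.entropy_se)  # zero residual dof

    def test_single_temperature_rejected(self):
        with pytest.raises(ValidityError):
            thermo_decomposition([(293.15, 4000.0), (293.15, 4100.0)])

    def test_rt0_table_per_row_scaling(self, constants):
        entries = [(288.15, 1.68), (293.15, 1.75), (303.15, 1.88)]
        per_row = energies_from_rt0_table(entries, constants)
        fixed = energies_from_rt0_table(entries, constants, per_row_rt=False)
        assert per_row[0][1] == pytest.approx(1.68 * 8.314 * 288.15, rel=1e-12)
        assert fixed[0][1] == pytest.approx(1.68 * constants.rt0, rel=1e-12)


class TestDatasetValidation:
    def test_non_monotone_concentrations(self, constants):
        with pytest.raises(ValidityError):
            IsothermDataset(Surfactant(2), 293.15, (2.0, 1.0), (1e-3, 2e-3),
                            constants.gamma0(293.15))

    def test_pressure_above_gamma0(self, constants):
        with pytest.raises(ValidityError):
            IsothermDataset(Surfactant(2), 293.15, (1.0, 2.0), (1e-3, 60e-3),
                            constants.gamma0(293.15))
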