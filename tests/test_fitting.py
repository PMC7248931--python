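"""Fitting tests: recovery, identifiability, extrapolation, Monte Carlo."""

import numpy as np
import pytest

from acdimer import (
    FepDataset,
    GlassDataset,
    IdentifiabilityError,
    ThermoState,
    VaporDecaySeries,
    default_config,
    extrapolate_monomer_shift,
    fit_fep_global,
    fit_glass_dataset,
    gibbs_energy,
    monte_carlo_uncertainty,
    simulate_fep_dataset,
    simulate_fep_ensemble,
    simulate_glass_dataset,
)

TRUE_DH, TRUE_DS = -15.4, -36.6
TRUE_DELTA_M, TRUE_DELTA_D = 3.76, 10.55


class TestGlobalFepFit:
    def test_noiseless_data_recovered_to_optimizer_tolerance(self):
        cfg = default_config(seed=7, n_points=400, sigma_delta=0.0, sigma_I=0.0)
        datasets, _ = simulate_fep_ensemble(cfg)
        fit = fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)
        assert abs(fit.thermo.dH - TRUE_DH) < 1e-3
        assert abs(fit.thermo.dS - TRUE_DS) < 1e-2
        assert fit.delta_D_per_dataset == pytest.approx([TRUE_DELTA_D] * 4, abs=1e-3)
        assert fit.p_corr_per_dataset == pytest.approx([0.002] * 4, abs=1e-4)

    def test_noisy_recovery_within_reported_uncertainty(self, small_ensemble):
        cfg, datasets, truths = small_ensemble
        fit = fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)
        assert abs(fit.thermo.dH - TRUE_DH) < 0.5
        assert abs(fit.thermo.dS - TRUE_DS) < 1.5
        assert abs(fit.delta_D_mean - TRUE_DELTA_D) < 0.10

    def test_dG0_consistent_with_thermo(self, small_ensemble):
        cfg, datasets, _ = small_ensemble
        fit = fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)
        assert fit.dG0 == pytest.approx(gibbs_energy(fit.thermo, 298.15), rel=1e-12)

    def test_single_temperature_is_unidentifiable(self):
        cfg = default_config(seed=11, temperatures=[353.15], n_points=300)
        datasets, _ = simulate_fep_ensemble(cfg)
        with pytest.raises(IdentifiabilityError, match="dH, dS"):
            fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)

    def test_baseline_offset_recovered_as_p_corr(self):
        cfg = default_config(seed=13, n_points=400, baseline_offset=0.002)
        datasets, _ = simulate_fep_ensemble(cfg)
        fit = fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)
        for pc in fit.p_corr_per_dataset:
            assert pc == pytest.approx(0.002, abs=1e-3)
            assert pc < 0.005

    def test_parameter_recovery_is_unbiased_over_replicates(self):
        """Mean estimates over replicates stay within one reported sigma."""
        dHs, dSs, dDs = [], [], []
        for seed in range(12):
            cfg = default_config(seed=seed, n_points=400)
            datasets, _ = simulate_fep_ensemble(cfg)
            fit = fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)
            dHs.append(fit.thermo.dH)
            dSs.append(fit.thermo.dS)
            dDs.append(fit.delta_D_mean)
        assert abs(np.mean(dHs) - TRUE_DH) < 0.5
        assert abs(np.mean(dSs) - TRUE_DS) < 1.5
        assert abs(np.mean(dDs) - TRUE_DELTA_D) < 0.1

    def test_mismatched_anchor_list_rejected(self, small_ensemble):
        cfg, datasets, _ = small_ensemble
        with pytest.raises(ValueError):
            fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset[:2])


class TestGlassFit:
    T0 = 303.15
    GRID = np.arange(303.15, 423.16, 5.0)

    def test_noiseless_series_recovers_truth(self):
        cfg = default_config(seed=21, sigma_delta=0.0, sigma_I=0.0)
        gd = simulate_glass_dataset(cfg, p0=0.03, T0=self.T0, T_grid=self.GRID)
        res = fit_glass_dataset(gd)
        assert res["thermo"].dH == pytest.approx(TRUE_DH, abs=1e-4)
        assert res["thermo"].dS == pytest.approx(TRUE_DS, abs=1e-3)
        assert res["delta_M"] == pytest.approx(TRUE_DELTA_M, abs=1e-4)
        assert res["delta_D"] == pytest.approx(TRUE_DELTA_D, abs=1e-4)

    def test_wall_adsorption_bias_makes_estimates_pressure_dependent(self):
        """With a T-dependent systematic, fitted parameters drift with p0 —
        the diagnostic that exposed surface interaction in glass tubes."""
        cfg = default_config(seed=22, sigma_delta=0.0, sigma_I=0.0)

        def drift(bias):
            ests = []
            for p0 in (0.03, 0.12):
                gd = simulate_glass_dataset(
                    cfg, p0=p0, T0=self.T0, T_grid=self.GRID,
                    bias_amplitude=bias, bias_scale_K=500.0,
                )
                ests.append(fit_glass_dataset(gd)["thermo"].dH)
            return abs(ests[1] - ests[0])

        assert drift(0.0) < 1e-4
        assert drift(2.0) > 0.05

    def test_too_few_points_rejected(self):
        gd = GlassDataset(p0=0.03, T0=303.15, points=[(300.0 + 30 * k, 8.0) for k in range(5)])
        with pytest.raises(ValueError, match="6"):
            fit_glass_dataset(gd)

    def test_narrow_temperature_span_rejected(self):
        gd = GlassDataset(p0=0.03, T0=303.15, points=[(300.0 + k, 8.0) for k in range(8)])
        with pytest.raises(ValueError, match="span"):
            fit_glass_dataset(gd)


class TestMonomerExtrapolation:
    def test_noiseless_150C_dataset_returns_generating_monomer_shift(self):
        cfg = default_config(seed=31, temperatures=[423.15], n_points=400,
                             sigma_delta=0.0, sigma_I=0.0)
        ds, _ = simulate_fep_dataset(cfg, 0)
        value = extrapolate_monomer_shift(ds, cfg.p0_per_dataset[0])
        assert value == pytest.approx(TRUE_DELTA_M, abs=1e-3)

    def test_no_dimerization_returns_mean_shift(self):
        # K = 0 regime: dH = T dS (dG ~ 0 would still dimerize); force a
        # hugely unfavorable equilibrium instead so the curve is flat
        cfg = default_config(seed=32, temperatures=[423.15], n_points=400,
                             sigma_delta=0.0, sigma_I=0.0)
        cfg.thermo = ThermoState(dH=20.0, dS=-30.0)
        ds, _ = simulate_fep_dataset(cfg, 0)
        value = extrapolate_monomer_shift(ds, cfg.p0_per_dataset[0])
        assert value == pytest.approx(float(np.mean(ds.dshift)), abs=1e-6)

    def test_noisy_intercept_within_tolerance(self):
        values = []
        for seed in range(10):
            cfg = default_config(seed=seed, temperatures=[423.15], n_points=600)
            ds, _ = simulate_fep_dataset(cfg, 0)
            values.append(extrapolate_monomer_shift(ds, cfg.p0_per_dataset[0]))
        assert abs(np.mean(values) - TRUE_DELTA_M) < 0.05

    def test_insufficient_pressure_span_rejected(self):
        t = 10.0 * np.arange(120)
        I = 500.0 * np.exp(-t / 1e6)  # essentially flat
        decay = VaporDecaySeries(t=t, I=I, t0=0.0, p0=0.5)
        ds = FepDataset(T=423.15, decay=decay, dshift=np.full(120, 7.0))
        with pytest.raises(ValueError, match="span"):
            extrapolate_monomer_shift(ds, 0.5)


@pytest.fixture(scope="module")
def base(small_ensemble):
    cfg, datasets, _ = small_ensemble
    return cfg, datasets, fit_fep_global(datasets, cfg.delta_M, cfg.p0_per_dataset)


class TestMonteCarlo:
    def test_zero_perturbation_gives_zero_sd(self, base):
        cfg, datasets, fit = base
        mc = monte_carlo_uncertainty(datasets, fit, n_iter=3, sys_frac=0.0, ds_frac=0.0, seed=1)
        assert mc.sd_dH == pytest.approx(0.0, abs=1e-12)
        assert mc.sd_dS == pytest.approx(0.0, abs=1e-12)
        assert mc.sd_dG0 == pytest.approx(0.0, abs=1e-12)

    def test_determinism_under_fixed_seed(self, base):
        cfg, datasets, fit = base
        mc1 = monte_carlo_uncertainty(datasets, fit, n_iter=8, seed=99)
        mc2 = monte_carlo_uncertainty(datasets, fit, n_iter=8, seed=99)
        assert mc1.sd_dH == mc2.sd_dH
        assert mc1.sd_dS == mc2.sd_dS
        assert mc1.cov_dH_dS == mc2.cov_dH_dS

    def test_enthalpy_entropy_correlation_structure(self, base):
        """The van't Hoff structure forces dH and dS errors to move
        together, leaving dG0 much better determined than dH."""
        cfg, datasets, fit = base
        mc = monte_carlo_uncertainty(datasets, fit, n_iter=40, seed=5)
        assert mc.cov_dH_dS > 0
        assert mc.sd_dG0 < 0.5 * mc.sd_dH
        # anchor-pressure uncertainty at the experimental 10%/5% level
        # produces dH spreads on the order of the reported half kcal/mol
        assert 0.02 < mc.sd_dH < 1.5

    def test_point_estimates_unchanged_by_mc(self, base):
        cfg, datasets, fit = base
        mc = monte_carlo_uncertainty(datasets, fit, n_iter=5, seed=2)
        assert mc.thermo == fit.thermo
        assert mc.delta_D_per_dataset == fit.delta_D_per_dataset

    def test_seed_is_mandatory(self, base):
        cfg, datasets, fit = base
        with pytest.raises(ValueError, match="seed"):
            monte_carlo_uncertainty(datasets, fit, n_iter=5)
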