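"""Estimators: self-inverse recovery, identifiability diagnostics, bootstrap."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from bzfit import (
    BFormExchangeFit,
    DatasetValidationError,
    ExchangeRateParams,
    GlobalShiftFit,
    MixtureComposition,
    RatioExchangeFit,
    TitrationDataset,
    ZFormExchangeFit,
    bootstrap_uncertainty,
    fit_exchange_bform,
    fit_exchange_vs_ratio,
    fit_exchange_zform,
    fit_global_shifts,
    solve_species,
)
from bzfit.fitting import stack_shift_datasets
from bzfit.recovery import recovery_study, summarize_recovery
from bzfit.synthetic import (
    SimulationSpec,
    simulate_dataset,
    spec_for_reference_system,
)
from bzfit.reference import BINDING_SYSTEMS, EXCHANGE_SYSTEMS, DEFAULT_EXCHANGE_RATES

RATES = ExchangeRateParams(**DEFAULT_EXCHANGE_RATES)


def _zero_noise(spec: SimulationSpec) -> SimulationSpec:
    return replace(spec, sigma_shift=0.0, sigma_fz=0.0, cv_kex=0.0)


class TestSelfInverse:
    def test_ratio_fit_recovers_generating_alpha(self):
        spec = _zero_noise(spec_for_reference_system(EXCHANGE_SYSTEMS[0], seed=1))
        with pytest.warns(UserWarning, match="under-determined"):
            result = fit_exchange_vs_ratio(simulate_dataset(spec))
        assert result.converged
        assert result.estimates["alpha"] == pytest.approx(1.15e-2, rel=1e-6)
        assert result.estimates["kex_zp"] == pytest.approx(RATES.kex_ZP, rel=1e-6)
        assert result.estimates["kex_zp2"] == pytest.approx(RATES.kex_ZP2, rel=1e-6)

    def test_zform_fit_recovers_alpha_and_k_bz1(self):
        """25-point f_Z curve pins both shape constants to 1e-4 relative."""
        spec = _zero_noise(
            replace(
                spec_for_reference_system(EXCHANGE_SYSTEMS[3], seed=1),
                fz_grid=tuple(np.round(np.linspace(0.04, 1.0, 25), 6)),
            )
        )
        result = fit_exchange_zform(simulate_dataset(spec))
        assert result.estimates["alpha"] == pytest.approx(0.154, rel=1e-4)
        assert result.estimates["k_bz1"] == pytest.approx(1.02, rel=1e-4)

    def test_bform_fit_recovers_alpha_and_k_bz1(self):
        spec = _zero_noise(
            replace(
                spec_for_reference_system(EXCHANGE_SYSTEMS[1], seed=1),
                fz_grid=tuple(np.round(np.linspace(0.03, 0.95, 25), 6)),
            )
        )
        result = fit_exchange_bform(simulate_dataset(spec))
        assert result.estimates["alpha"] == pytest.approx(1.42, rel=1e-4)
        assert result.estimates["k_bz1"] == pytest.approx(0.4, rel=1e-4)

    def test_global_fit_recovers_all_three_constants(self):
        system = BINDING_SYSTEMS[0]
        spec = _zero_noise(spec_for_reference_system(system, seed=1))
        result = fit_global_shifts([simulate_dataset(spec)])
        assert result.estimates["kd_bp"] == pytest.approx(system.kd_bp_uM, rel=1e-3)
        assert result.estimates["kd_zp2"] == pytest.approx(system.kd_zp2_uM, rel=1e-3)
        assert result.estimates["k_bz1"] == pytest.approx(system.k_bz1, rel=1e-3)

    def test_global_fit_recovers_per_probe_shifts(self):
        spec = _zero_noise(spec_for_reference_system(BINDING_SYSTEMS[3], seed=1))
        result = fit_global_shifts([simulate_dataset(spec)])
        est = result.estimator
        for pair in spec.shifts:
            fitted = est.probe_shifts_[pair.probe_id]
            assert fitted.delta_B == pytest.approx(pair.delta_B, abs=1e-6)
            assert fitted.delta_Z == pytest.approx(pair.delta_Z, abs=1e-6)


class TestIdentifiability:
    def test_alpha_one_boundary_is_linear_mixing(self, chi_grid_20):
        """Data generated at alpha = 1 look like linear mixing of the two
        limiting rates; the fit reproduces the curve and lands near 1."""
        spec = SimulationSpec(
            observable_kind="kex_vs_chi", alpha=1.0, rates=RATES,
            chi_grid=chi_grid_20, seed=0, cv_kex=0.0,
        )
        ds = simulate_dataset(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit_exchange_vs_ratio(ds)
        assert result.objective < 1e-12
        assert result.estimates["alpha"] == pytest.approx(1.0, rel=1e-2)

    def test_flat_bform_curve_is_flagged_rank_deficient(self):
        """kex_BP == kex_B removes all signal: alpha and K_BZ1 cannot be
        estimated and the fit says so instead of returning silent numbers."""
        flat = ExchangeRateParams(kex_B=30.0, kex_BP=30.0)
        spec = SimulationSpec(
            observable_kind="kex_bform", alpha=0.5, k_bz1=1.0, rates=flat,
            fz_grid=tuple(np.round(np.linspace(0.05, 0.9, 15), 6)),
            seed=0, cv_kex=0.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit_exchange_bform(simulate_dataset(spec))
        assert "rank-deficient" in result.flags or "non-identifiable" in result.flags

    def test_single_point_dataset_warns_and_flags(self):
        ds = TitrationDataset(
            "kex_vs_chi",
            pd.DataFrame({"chi": [1.0], "f_z": [np.nan], "kex_s1": [5.0]}),
        )
        with pytest.warns(UserWarning, match="under-determined"):
            result = fit_exchange_vs_ratio(ds)
        assert "few-points" in result.flags
        assert "non-identifiable" in result.flags

    def test_log_and_linear_parameterizations_agree(self):
        """On zero-noise data the optimum is parameterization-invariant."""
        spec = _zero_noise(spec_for_reference_system(BINDING_SYSTEMS[3], seed=1))
        ds = simulate_dataset(spec)
        a = fit_global_shifts([ds], log_scale=True)
        b = fit_global_shifts([ds], log_scale=False)
        for name in ("kd_bp", "kd_zp2", "k_bz1"):
            assert a.estimates[name] == pytest.approx(b.estimates[name], rel=1e-6)

    def test_objective_profile_is_unimodal_around_optimum(self):
        """The objective along the K_BZ1 axis rises on both sides of the
        fitted optimum on a +/- 30% grid."""
        spec = replace(
            spec_for_reference_system(EXCHANGE_SYSTEMS[3], seed=3),
            fz_grid=tuple(np.round(np.linspace(0.04, 1.0, 25), 6)),
        )
        ds = simulate_dataset(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit_exchange_zform(ds, fixed=RATES)
        est = result.estimator
        x = ds.data["f_z"].to_numpy()
        y = ds.data["kex_s1"].to_numpy()
        k_hat = result.estimates["k_bz1"]
        grid = k_hat * np.linspace(0.7, 1.3, 13)
        profile = est.objective_profile("k_bz1", grid, x, y)
        i_min = int(np.argmin(profile))
        assert abs(grid[i_min] - k_hat) / k_hat < 0.06
        assert np.all(np.diff(profile[: i_min + 1]) <= 1e-12)
        assert np.all(np.diff(profile[i_min:]) >= -1e-12)


class TestMonteCarloRecovery:
    def test_estimator_consistency_with_denser_curves(self):
        """Median absolute error of alpha shrinks as the chi grid doubles."""
        errors = []
        for n_points in (12, 24, 48):
            grid = tuple(np.round(np.linspace(0.1, 1.95, n_points), 6))
            spec = SimulationSpec(
                observable_kind="kex_vs_chi", alpha=0.5, rates=RATES,
                chi_grid=grid, seed=0,
            )
            df = recovery_study(spec, 40, seed=11, fixed=RATES)
            errors.append(float((df["alpha"] - 0.5).abs().median()))
        assert errors[0] > errors[1] > errors[2]

    def test_bform_k_bz1_recovery_under_noise(self):
        """200 replicates at 5% noise keep the median K_BZ1 error under 15%."""
        spec = SimulationSpec(
            observable_kind="kex_bform", alpha=0.3, k_bz1=0.4, rates=RATES,
            fz_grid=tuple(np.round(np.linspace(0.05, 0.92, 12), 6)), seed=0,
        )
        df = recovery_study(spec, 200, seed=42, fixed=RATES)
        summary = summarize_recovery(df).set_index("parameter")
        assert summary.loc["k_bz1", "median_rel_error"] < 0.15


class TestGlobalFitStructure:
    def test_inconsistent_composition_grids_rejected(self):
        ds1 = simulate_dataset(
            _zero_noise(spec_for_reference_system(BINDING_SYSTEMS[0], seed=1))
        )
        shrunk = replace(
            _zero_noise(spec_for_reference_system(BINDING_SYSTEMS[0], seed=1)),
            compositions=tuple((p * 2, n) for p, n in [(1.0, 2.0), (2.0, 2.0)]),
        )
        ds2 = simulate_dataset(shrunk)
        with pytest.raises(DatasetValidationError, match="inconsistent"):
            stack_shift_datasets([ds1, ds2])

    def test_wrong_observable_kind_rejected(self):
        ds = simulate_dataset(
            _zero_noise(spec_for_reference_system(EXCHANGE_SYSTEMS[0], seed=1))
        )
        with pytest.raises(DatasetValidationError):
            fit_exchange_zform(ds)
        with pytest.raises(DatasetValidationError):
            fit_global_shifts([ds])

    def test_protein_denominator_convention(self):
        """Fitting data generated with the protein-normalized Z fraction
        recovers truth when the fit uses the same convention."""
        system = BINDING_SYSTEMS[3]
        spec = _zero_noise(spec_for_reference_system(system, seed=1))
        ds = simulate_dataset(spec)
        params = spec.model_params()
        df = ds.data.copy()
        fz_rows = ds.fz_mask()
        for idx in df.index[fz_rows]:
            state = solve_species(
                params,
                MixtureComposition(df.loc[idx, "P_total_uM"], df.loc[idx, "N_total_uM"]),
            )
            df.loc[idx, "f_z"] = state.f_Z_protein
        ds_prot = TitrationDataset("shift_and_fz", df, ds.metadata)
        result = fit_global_shifts([ds_prot], config={"fz_denominator": "protein"})
        assert result.estimates["kd_bp"] == pytest.approx(system.kd_bp_uM, rel=1e-3)
        assert result.estimates["k_bz1"] == pytest.approx(system.k_bz1, rel=1e-3)

    def test_omitting_fz_data_degrades_kd_zp2_precision(self):
        """The f_Z curves anchor the conformational split: dropping them
        widens the (cold multi-start) bootstrap interval on Kd_ZP2."""
        system = BINDING_SYSTEMS[3]
        spec = spec_for_reference_system(system, seed=5, n_probes=4)
        ds = simulate_dataset(spec)
        shifts_only = TitrationDataset(
            "shift_and_fz", ds.data[ds.shift_mask()].reset_index(drop=True), ds.metadata
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_full = fit_global_shifts([ds])
            fit_shift = fit_global_shifts([shifts_only])
            # cold multi-start refits: warm-started bootstrap cannot explore
            # the flat valley left by the missing f_Z information
            boot_full = bootstrap_uncertainty(
                fit_full, [ds], n_boot=100, seed=9, n_starts=4
            )
            boot_shift = bootstrap_uncertainty(
                fit_shift, [shifts_only], n_boot=100, seed=9, n_starts=4
            )
        width = lambda b: b.loc["kd_zp2", "p84"] - b.loc["kd_zp2", "p16"]  # noqa: E731
        assert width(boot_shift) / width(boot_full) > 1.0


class TestBootstrap:
    @pytest.fixture
    def noisy_ratio_fit(self, chi_grid_20):
        spec = SimulationSpec(
            observable_kind="kex_vs_chi", alpha=0.5, rates=RATES,
            chi_grid=chi_grid_20, seed=7,
        )
        ds = simulate_dataset(spec)
        return ds, fit_exchange_vs_ratio(ds, fixed=RATES)

    def test_fixed_seed_reproduces_intervals(self, noisy_ratio_fit):
        ds, fit = noisy_ratio_fit
        a = bootstrap_uncertainty(fit, ds, n_boot=100, seed=3)
        b = bootstrap_uncertainty(fit, ds, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_intervals_collapse(self, chi_grid_20):
        spec = SimulationSpec(
            observable_kind="kex_vs_chi", alpha=0.5, rates=RATES,
            chi_grid=chi_grid_20, seed=7, cv_kex=0.0,
        )
        ds = simulate_dataset(spec)
        fit = fit_exchange_vs_ratio(ds, fixed=RATES)
        boot = bootstrap_uncertainty(fit, ds, n_boot=100, seed=3)
        width = boot.loc["alpha", "p84"] - boot.loc["alpha", "p16"]
        assert width < 1e-6 * fit.estimates["alpha"]

    def test_small_n_boot_rejected(self, noisy_ratio_fit):
        ds, fit = noisy_ratio_fit
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_uncertainty(fit, ds, n_boot=50, seed=0)

    def test_nominal_68_interval_coverage(self, chi_grid_20):
        """Across 200 seeded synthetic replicates the 16-84 percentile
        interval covers the generating alpha at close to nominal rate."""
        base = SimulationSpec(
            observable_kind="kex_vs_chi", alpha=0.5, rates=RATES,
            chi_grid=chi_grid_20, seed=0,
        )
        seeds = np.random.SeedSequence(123).generate_state(200) % (2**31)
        hits = n_ok = 0
        for s in seeds:
            ds = simulate_dataset(replace(base, seed=int(s)))
            fit = fit_exchange_vs_ratio(ds, fixed=RATES)
            boot = bootstrap_uncertainty(fit, ds, n_boot=100, seed=int(s) + 1)
            n_ok += 1
            if boot.loc["alpha", "p16"] <= 0.5 <= boot.loc["alpha", "p84"]:
                hits += 1
        assert n_ok == 200
        assert 0.60 <= hits / n_ok <= 0.76


class TestSklearnProtocol:
    def test_clone_and_params_roundtrip(self):
        est = ZFormExchangeFit(n_starts=4, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(n_starts=2)
        assert est.n_starts == 2

    def test_fit_predict_with_column_vector_X(self):
        spec = _zero_noise(spec_for_reference_system(EXCHANGE_SYSTEMS[0], seed=1))
        ds = simulate_dataset(spec)
        x = ds.data["chi"].to_numpy()[:, None]
        y = ds.data["kex_s1"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = RatioExchangeFit().fit(x, y)
        assert est.alpha_ == pytest.approx(1.15e-2, rel=1e-6)
        np.testing.assert_allclose(est.predict(x), y, rtol=1e-8)

    def test_unfitted_predict_raises(self):
        with pytest.raises(Exception):
            BFormExchangeFit().predict([0.1, 0.2])

    def test_global_estimator_predict_matches_training_targets(self):
        spec = _zero_noise(spec_for_reference_system(BINDING_SYSTEMS[0], seed=1))
        ds = simulate_dataset(spec)
        X, y, sigma = stack_shift_datasets([ds])
        est = GlobalShiftFit().fit(X, y, sample_weight=1.0 / sigma**2)
        np.testing.assert_allclose(est.predict(X), y, atol=1e-8)
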