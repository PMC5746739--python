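"""Flux fitting: objective correctness, recovery, Monte Carlo, continuation."""

import numpy as np
import pytest

from hetflux import synth
from hetflux.fitting import (
    CISettings,
    FitSettings,
    MonteCarloSettings,
    Objective,
    continuation_ci,
    fit_fluxes,
    monte_carlo_fit,
    ssr,
)
from hetflux.heterogeneity import MixtureScenario, simulate_mixture_dataset
from hetflux.midtools import MeasurementSet
from hetflux.network import complete_fluxes
from hetflux.simulate import simulate_isotopomers_emu, simulate_mids


def toy_dataset(net, param, tracer, free_values, mets=("A", "B", "C"), sd=0.01):
    dists = simulate_isotopomers_emu(
        net, complete_fluxes(param, free_values), tracer, list(mets)
    )
    ms = MeasurementSet.from_isotopomers(dists)
    ms.df["sd"] = sd
    return ms


@pytest.fixture(scope="module")
def canonical_dataset(canonical, table1_state, panel_targets):
    net, param = canonical
    state, values = table1_state
    tracer = synth.glucose_tracer(u13c=0.2, c1=0.8)
    mids = simulate_mids(net, state, tracer, list(panel_targets.values()))
    data = (
        MeasurementSet.from_mids(mids, targets=panel_targets)
        .with_flux_measurements({"v_upt": 100.0})
        .assign_sd()
    )
    return data, tracer, values


class TestSSR:
    def test_zero_at_generating_fluxes(self, fig2, toy_tracer):
        net, param = fig2
        data = toy_dataset(net, param, toy_tracer, [0.4, 0.2])
        assert ssr(net, param, [0.4, 0.2], data, toy_tracer) == pytest.approx(
            0.0, abs=1e-16
        )

    def test_one_sd_perturbation_scores_one(self, fig1, toy_tracer):
        net, param = fig1
        data = toy_dataset(net, param, toy_tracer, [0.3])
        data.df.loc[0, "value"] += data.df.loc[0, "sd"]
        assert ssr(net, param, [0.3], data, toy_tracer) == pytest.approx(1.0)

    def test_generating_fluxes_minimize_over_grid(self, fig2, toy_tracer):
        # grid-search oracle: no probed flux vector beats the truth
        net, param = fig2
        truth = [0.55, 0.35]
        data = toy_dataset(net, param, toy_tracer, truth)
        obj = Objective(net, param, data, toy_tracer)
        best = obj.ssr(np.array(truth))
        for n in np.linspace(0, 1, 9):
            for x in np.linspace(0, 0.9, 7):
                assert best <= obj.ssr(np.array([n, x])) + 1e-12

    def test_zero_sd_is_rejected(self, fig1, toy_tracer):
        net, param = fig1
        data = toy_dataset(net, param, toy_tracer, [0.3])
        data.df["sd"] = 0.0
        with pytest.raises(ValueError, match="SD"):
            Objective(net, param, data, toy_tracer)

    def test_reported_ssr_matches_reevaluation(self, fig2, toy_tracer):
        net, param = fig2
        data = toy_dataset(net, param, toy_tracer, [0.6, 0.4])
        data.df["value"] += np.random.default_rng(1).normal(0, 0.01, len(data.df))
        fit = fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=5))
        assert fit.ssr == pytest.approx(
            ssr(net, param, fit.values, data, toy_tracer), rel=1e-12
        )


class TestFitting:
    def test_underdetermined_data_is_rejected(self, fig2, toy_tracer):
        net, param = fig2
        data = toy_dataset(net, param, toy_tracer, [0.4, 0.2])
        data.df = data.df.iloc[:2]
        with pytest.raises(ValueError, match="free fluxes"):
            fit_fluxes(net, param, data, toy_tracer)

    def test_averaged_single_flux_data_fits_weighted_flux(self, fig1, toy_tracer):
        # with one variable flux, labelling is linear in the flux: fitting the
        # 50:50 average of the extreme datasets recovers the mean exactly
        net, param = fig1
        sc = MixtureScenario(
            [
                (complete_fluxes(param, [0.0]), 0.5),
                (complete_fluxes(param, [1.0]), 0.5),
            ]
        )
        data = simulate_mixture_dataset(
            net, sc, toy_tracer, ["A", "B", "C"], kind="isotopomer"
        ).assign_sd()
        fit = fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=5))
        assert fit.values[0] == pytest.approx(0.5, abs=1e-6)

    def test_averaged_two_flux_data_misfits_weighted_flux(self, fig2, toy_tracer):
        # the same construction with an exchange flux active no longer
        # recovers the weighted fluxes: labelling is non-linear in the fluxes
        net, param = fig2
        sc = MixtureScenario(
            [
                (complete_fluxes(param, [0.0, 0.5]), 0.5),
                (complete_fluxes(param, [1.0, 0.5]), 0.5),
            ]
        )
        data = simulate_mixture_dataset(
            net, sc, toy_tracer, ["A", "B", "C"], kind="isotopomer"
        ).assign_sd()
        fit = fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=10))
        assert abs(fit.values[0] - 0.5) > 0.05
        assert fit.ssr > 10.0  # the average is not reproducible by any state

    def test_canonical_noise_free_recovery(self, canonical, canonical_dataset):
        net, param = canonical
        data, tracer, truth = canonical_dataset
        fit = fit_fluxes(net, param, data, tracer, FitSettings(multistart=20, seed=1))
        np.testing.assert_allclose(fit.values, truth, rtol=1e-3)

    def test_deterministic_under_fixed_seed(self, fig2, toy_tracer):
        net, param = fig2
        data = toy_dataset(net, param, toy_tracer, [0.7, 0.6])
        fits = [
            fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=6, seed=9))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].values, fits[1].values)


class TestParameterRecoveryProperty:
    def test_random_canonical_states_recover(self, canonical, panel_targets):
        # noise-free identifiability across the physiological flux box
        net, param = canonical
        tracer = synth.glucose_tracer(u13c=0.2, c1=0.8)
        rng = np.random.default_rng(2024)
        box = {
            "v_upt.net": (60, 150),
            "v_bm.net": (3, 11),
            "v_g6pdh.net": (10, 90),
            "v_ppc.net": (20, 140),
            "v_icl.net": (4, 45),
        }
        states = synth.random_feasible_states(param, 20, rng, box=box)
        for values, state in states:
            mids = simulate_mids(net, state, tracer, list(panel_targets.values()))
            data = (
                MeasurementSet.from_mids(mids, targets=panel_targets)
                .with_flux_measurements({"v_upt": state.net["v_upt"]})
                .assign_sd()
            )
            fit = fit_fluxes(
                net, param, data, tracer, FitSettings(multistart=20, seed=5)
            )
            np.testing.assert_allclose(
                fit.values, values, rtol=5e-3, err_msg=str(values)
            )


class TestMonteCarlo:
    def test_protocol_and_determinism(self, fig1, toy_tracer):
        net, param = fig1
        data = toy_dataset(net, param, toy_tracer, [0.4])
        mc = MonteCarloSettings(replicates=100, seed=17)
        runs = [
            monte_carlo_fit(net, param, data, toy_tracer, mc, FitSettings(multistart=3))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].mc_values, runs[1].mc_values)
        assert runs[0].mc_values.shape == (100, 1)

    def test_noise_floor_rule(self, fig1, toy_tracer):
        # replicate noise must follow sd = max(0.01 * value, 0.001)
        net, param = fig1
        data = toy_dataset(net, param, toy_tracer, [0.4])
        truth = data.df["value"].to_numpy()
        expected_sd = np.maximum(0.01 * np.abs(truth), 0.001)
        mc = MonteCarloSettings(replicates=200, seed=3)
        rng = np.random.default_rng(mc.seed)
        draws = np.array(
            [truth + rng.normal(0.0, expected_sd) for _ in range(200)]
        )
        emp_sd = draws.std(axis=0, ddof=1)
        np.testing.assert_allclose(emp_sd, expected_sd, rtol=0.25)

    def test_mc_mean_tracks_point_estimate(self, canonical, canonical_dataset):
        net, param = canonical
        data, tracer, truth = canonical_dataset
        base = fit_fluxes(net, param, data, tracer, FitSettings(multistart=6, seed=1))
        mc = monte_carlo_fit(
            net, param, data, tracer,
            MonteCarloSettings(replicates=30, seed=8),
            FitSettings(multistart=6, seed=1),
            base=base,
        )
        # sampling-theory check: the MC mean sits within a few standard
        # errors of the noise-free point estimate
        se = mc.mc_sd / np.sqrt(30)
        assert (np.abs(mc.mc_mean - base.values) < 4 * se + 1e-9).all()

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MonteCarloSettings(replicates=1)
        with pytest.raises(ValueError):
            MonteCarloSettings(rel=0.0)


class TestContinuationCI:
    def test_matches_analytic_interval_in_linear_model(self, fig1, toy_tracer):
        # the single-flux toy is linear: residuals r(n) = (sim(n) - y)/sd with
        # sim affine in n, so the 95% profile interval is
        # n_hat +/- sqrt(3.84) / |dr/dn|
        net, param = fig1
        data = toy_dataset(net, param, toy_tracer, [0.4])
        fit = fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=4))
        nominal = 0.001
        ci = continuation_ci(
            net, param, fit, data, toy_tracer, CISettings(nominal_sd=nominal)
        )
        obj = Objective(net, param, data, toy_tracer)
        eps = 1e-6
        grad = (obj.simulate([0.4 + eps]) - obj.simulate([0.4 - eps])) / (2 * eps)
        from scipy.stats import chi2

        half = np.sqrt(chi2.ppf(0.95, 1)) / np.linalg.norm(grad / nominal)
        lo, hi = ci["R1.net"]
        assert hi - lo == pytest.approx(2 * half, rel=0.01)
        assert (lo + hi) / 2 == pytest.approx(0.4, abs=1e-6)

    def test_truth_inside_interval_for_noise_free_data(self, fig2, toy_tracer):
        net, param = fig2
        truth = [0.6, 0.3]
        data = toy_dataset(net, param, toy_tracer, truth)
        fit = fit_fluxes(net, param, data, toy_tracer, FitSettings(multistart=6))
        ci = continuation_ci(net, param, fit, data, toy_tracer, CISettings())
        for value, name in zip(truth, param.free_names):
            lo, hi = ci[name]
            assert lo <= value <= hi

    def test_anaplerosis_less_precise_than_uptake(
        self, canonical, canonical_dataset
    ):
        net, param = canonical
        data, tracer, truth = canonical_dataset
        fit = fit_fluxes(net, param, data, tracer, FitSettings(multistart=6, seed=1))
        ci = continuation_ci(net, param, fit, data, tracer, CISettings())
        width = {k: hi - lo for k, (lo, hi) in ci.items()}
        # among the labelling-determined fluxes (uptake is pinned by its own
        # rate measurement), the anaplerotic flux is the least precise
        assert width["v_ppc.net"] > width["v_g6pdh.net"]
        assert width["v_ppc.net"] > width["v_bm.net"]
        assert width["v_icl.net"] > width["v_bm.net"]

    def test_coverage_under_replicate_noise(self, fig2, toy_tracer):
        # 95% continuation CI should cover the generating flux in most
        # noisy datasets (binomial check at modest replicate count)
        net, param = fig2
        truth = np.array([0.5, 0.4])
        base = toy_dataset(net, param, toy_tracer, truth)
        values = base.df["value"].to_numpy()
        sd = np.maximum(0.01 * np.abs(values), 0.001)
        rng = np.random.default_rng(101)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            data = base.copy()
            data.df["value"] = values + rng.normal(0, sd)
            data.df["sd"] = sd
            fit = fit_fluxes(
                net, param, data, toy_tracer, FitSettings(multistart=4, seed=0)
            )
            ci = continuation_ci(
                net, param, fit, data, toy_tracer, CISettings(nominal_sd=None)
            )
            lo, hi = ci["R1.net"]
            covered += lo <= truth[0] <= hi
        assert covered >= int(0.85 * n_rep)
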