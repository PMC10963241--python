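"""Estimation-layer tests: objectives, multistart, two-step fit, BIC, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdkin import (
    AdsorptionIsotherm,
    InverseMMRegressor,
    KineticDataset,
    Prior,
    SurfaceCrowdingRegressor,
    bic,
    bootstrap_ci,
    compare_models,
    fit_adsorption,
    fit_kinetics,
    map_objective,
    multistart_optimize,
    weighted_ssr,
)
from crowdkin.estimation import ZeroVarianceError
from crowdkin.model import inv_mm_rate_grid
from crowdkin.params import DEFAULT_ET_GRID, InvMMParameters
from crowdkin.simulate import SimulationConfig, generate_adsorption, generate_kinetics

PARAM_NAMES = ("K_a", "Gamma", "K_c", "k_cat_uc", "k_cat_c")


def two_step(params, cv, seed, n_starts=12, E_grid=None):
    E_grid = E_grid or DEFAULT_ET_GRID["30C"]
    kin = generate_kinetics(SimulationConfig(params=params, E_T_grid=E_grid,
                                             cv=cv, seed=seed))
    ads = generate_adsorption(params, E_grid, 500.0, cv=cv, seed=seed + 1000)
    ra = fit_adsorption(ads, n_starts=8, seed=seed)
    rk = fit_kinetics(kin, prior=ra.flags["prior"], gamma_upper=ra.flags["gamma_upper"],
                      n_starts=n_starts, seed=seed)
    return ra, rk


class TestObjectives:
    def test_perfect_fit_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert weighted_ssr(y, y, np.ones(3)) == 0.0

    def test_hand_arithmetic(self):
        # residuals (1, 2), variances (1, 4) -> 1 + 1 = 2
        assert weighted_ssr([1.0, 2.0], [0.0, 0.0], [1.0, 4.0]) == pytest.approx(2.0)

    @given(st.integers(2, 30), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        obs, pred = rng.normal(size=n), rng.normal(size=n)
        var = rng.uniform(0.1, 2.0, size=n)
        loop = sum((o - p) ** 2 / v for o, p, v in zip(obs, pred, var))
        assert weighted_ssr(obs, pred, var) == pytest.approx(loop, rel=1e-12)

    def test_zero_variance_raises_with_guidance(self):
        with pytest.raises(ZeroVarianceError, match="floor"):
            weighted_ssr([1.0], [0.0], [0.0])

    def test_map_reduces_to_ssr_with_empty_prior(self):
        y = np.array([1.0, 2.0])
        out = map_objective(np.zeros(3), y, np.ones(2), lambda z: y * 0.5, Prior.empty())
        assert out == pytest.approx(weighted_ssr(y, y * 0.5, np.ones(2)))

    def test_map_zero_at_prior_mean_with_perfect_fit(self):
        y = np.array([1.0, 2.0])
        prior = Prior(mu=np.zeros(2), V_mu=np.eye(2), active_idx=(0, 1))
        assert map_objective(np.zeros(3), y, np.ones(2), lambda z: y, prior) == 0.0

    def test_map_matches_independent_quadratic_forms(self, rng):
        mu = rng.normal(size=2)
        A = rng.normal(size=(2, 2))
        V = A @ A.T + 2 * np.eye(2)
        prior = Prior(mu=mu, V_mu=V, active_idx=(0, 2))
        z = rng.normal(size=4)
        y, pred, var = rng.normal(size=5), rng.normal(size=5), rng.uniform(0.5, 2, 5)
        got = map_objective(z, y, var, lambda _: pred, prior)
        d = z[[0, 2]] - mu
        expect = np.sum((y - pred) ** 2 / var) + d @ np.linalg.inv(V) @ d
        assert got == pytest.approx(expect, rel=1e-10)

    def test_prior_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            Prior(mu=np.zeros(2), V_mu=np.eye(3), active_idx=(0, 1))


class TestMultistart:
    def test_convex_quadratic_all_starts_agree(self):
        x, f, rec = multistart_optimize(lambda z: float(np.sum((z - 0.3) ** 2)),
                                        [(-2, 2)] * 3, n_starts=16, seed=0)
        assert f == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(x, 0.3, atol=1e-5)
        assert rec.converged_fraction == 1.0

    def test_multimodal_global_optimum_found(self):
        def rastrigin(z):
            return float(20 + np.sum(z * z - 10 * np.cos(2 * np.pi * z)))

        x, f, _ = multistart_optimize(rastrigin, [(-2.048, 2.048)] * 2,
                                      n_starts=64, seed=1)
        assert f == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(x, 0.0, atol=1e-4)

    def test_determinism(self):
        obj = lambda z: float(np.sum(np.sin(3 * z) + z * z))
        out1 = multistart_optimize(obj, [(-3, 3)] * 2, n_starts=8, seed=42)
        out2 = multistart_optimize(obj, [(-3, 3)] * 2, n_starts=8, seed=42)
        assert np.array_equal(out1[2].x0, out2[2].x0)
        assert out1[1] == out2[1]

    def test_bad_bounds_raise(self):
        with pytest.raises(ValueError):
            multistart_optimize(lambda z: 0.0, [(0.0, np.inf)], n_starts=2, seed=0)


class TestBIC:
    def test_penalty_arithmetic_equal_fit(self):
        # same ssr: the 3-parameter model wins by exactly 2 ln(60)
        assert bic(1.0, 60, 5) - bic(1.0, 60, 3) == pytest.approx(2 * np.log(60))

    def test_halved_ssr_overcomes_two_extra_params(self):
        delta = bic(0.5, 60, 5) - bic(1.0, 60, 3)
        assert delta == pytest.approx(60 * np.log(0.5) + 2 * np.log(60))
        assert delta < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bic(0.0, 60, 3)
        with pytest.raises(ValueError):
            bic(1.0, 3, 5)


class TestAdsorptionFit:
    def test_noiseless_recovery(self, wt_params):
        ads = generate_adsorption(wt_params, DEFAULT_ET_GRID["30C"], 500.0, cv=0.0, seed=0)
        res = fit_adsorption(ads, n_starts=8, seed=0)
        assert res.params["K_a"] == pytest.approx(wt_params.K_a, rel=1e-4)
        assert res.params["Gamma"] == pytest.approx(wt_params.Gamma, rel=1e-4)

    def test_noisy_fit_matches_grid_search_oracle(self, wt_params):
        ads = generate_adsorption(wt_params, DEFAULT_ET_GRID["30C"], 500.0, cv=0.05, seed=3)
        X, y, sd = ads.to_Xy()
        est = AdsorptionIsotherm(n_starts=8, random_state=1).fit(X, y, y_sd=sd)
        # dense log-grid search over (K_a, Gamma) as the independent optimum
        from crowdkin.model import adsorbed_complex_grid

        V = np.maximum(sd, 0.01 * y.max()) ** 2
        ka_grid = np.logspace(-3, -1, 200)
        g_grid = np.logspace(-2.5, -0.5, 200)
        best = (np.inf, None, None)
        for ka in ka_grid:
            pred = adsorbed_complex_grid(ka, g_grid[:, None], X[None, :, 0], X[None, :, 1])
            cost = np.sum((y[None, :] - pred) ** 2 / V[None, :], axis=1)
            j = int(np.argmin(cost))
            if cost[j] < best[0]:
                best = (cost[j], ka, g_grid[j])
        assert est.result_.objective <= best[0] + 1e-9
        assert est.K_a_ == pytest.approx(best[1], rel=0.02)    # within grid resolution
        assert est.Gamma_ == pytest.approx(best[2], rel=0.02)

    def test_plateau_only_design_flags_weak_Ka(self, wt_params):
        # all E_T far above capacity: Gamma identified, K_a basically free
        E = np.array([2000.0, 3000.0, 4000.0, 6000.0, 8000.0])
        ads = generate_adsorption(wt_params, E, 500.0, cv=0.01, seed=5)
        res = fit_adsorption(ads, n_starts=8, seed=0)
        assert res.params["Gamma"] == pytest.approx(wt_params.Gamma, rel=0.1)
        assert res.flags.get("K_a_weakly_identified", False)


class TestKineticFit:
    def test_noiseless_two_step_recovery(self, wt_params):
        _, rk = two_step(wt_params, cv=0.0, seed=1)
        for name in PARAM_NAMES:
            assert getattr(rk.params, name) == pytest.approx(getattr(wt_params, name), rel=1e-2), name
        # tighter: well under 1% for all five
        rel = [abs(getattr(rk.params, n) / getattr(wt_params, n) - 1) for n in PARAM_NAMES]
        assert max(rel) < 1e-2

    def test_missing_prior_refused_with_workflow_hint(self, wt_params):
        kin = generate_kinetics(SimulationConfig(params=wt_params, cv=0.0, seed=0))
        X, y, sd = kin.to_Xy()
        with pytest.raises(ValueError, match="two-step"):
            SurfaceCrowdingRegressor(prior=None).fit(X, y, y_sd=sd)

    def test_prior_at_unpenalized_optimum_does_not_move_it(self, wt_params):
        kin = generate_kinetics(SimulationConfig(params=wt_params, cv=0.0, seed=2))
        X, y, sd = kin.to_Xy()
        free = SurfaceCrowdingRegressor(prior=Prior.empty(), n_starts=10,
                                        random_state=0).fit(X, y, y_sd=sd)
        z_free = free.result_.log_params
        anchored = SurfaceCrowdingRegressor(
            prior=Prior(mu=z_free[:2], V_mu=np.eye(2) * 1e-4, active_idx=(0, 1)),
            n_starts=10, random_state=0).fit(X, y, y_sd=sd)
        assert np.allclose(anchored.result_.log_params, z_free, atol=1e-4)

    def test_gamma_capped_by_adsorption_capacity(self, wt_params):
        kin = generate_kinetics(SimulationConfig(params=wt_params, cv=0.0, seed=3))
        X, y, sd = kin.to_Xy()
        cap = wt_params.Gamma * 0.5  # deliberately below truth
        est = SurfaceCrowdingRegressor(prior=Prior.empty(), gamma_upper=cap,
                                       n_starts=8, random_state=0).fit(X, y, y_sd=sd)
        assert est.params_.Gamma <= cap * (1 + 1e-9)
        assert est.result_.flags.get("gamma_at_upper_bound", False)

    def test_crowding_constraint_holds(self, wt_params):
        _, rk = two_step(wt_params, cv=0.05, seed=9)
        assert rk.params.k_cat_c <= rk.params.k_cat_uc


class TestModelSelection:
    def test_bic_prefers_crowding_model_on_crowded_data(self, wt_params):
        kin = generate_kinetics(SimulationConfig(params=wt_params, cv=0.05, seed=11))
        ads = generate_adsorption(wt_params, DEFAULT_ET_GRID["30C"], 500.0, cv=0.05, seed=12)
        ra = fit_adsorption(ads, n_starts=8, seed=0)
        cmp = compare_models(kin, prior=ra.flags["prior"],
                             gamma_upper=ra.flags["gamma_upper"], n_starts=8, seed=0)
        assert cmp["selected"] == "sc"
        assert cmp["delta_bic"] < 0

    def test_no_strong_preference_on_saturating_data(self):
        # data generated WITHOUT inhibition: the extra crowding parameters
        # should not be strongly favored (majority of seeds pick the simpler law)
        truth = InvMMParameters(k_inv=0.5, Gamma_inv=0.1, K_inv=80.0)
        E = np.array(DEFAULT_ET_GRID["30C"])
        N0s = np.array([200.0, 500.0, 950.0, 1900.0])
        EE, NN = np.meshgrid(E, N0s, indexing="ij")
        mu = inv_mm_rate_grid(truth, EE.ravel(), NN.ravel())
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            reps = np.maximum(mu[:, None] * (1 + 0.05 * rng.standard_normal((mu.size, 3))), 0)
            kin = KineticDataset(pd.DataFrame({
                "enzyme_nM": EE.ravel(), "substrate_cm2_per_L": NN.ravel(),
                "rate_mA260_per_min": reps.mean(axis=1),
                "sd": reps.std(axis=1, ddof=1), "n": 3}))
            cmp = compare_models(kin, prior=Prior.empty(), n_starts=8, seed=seed)
            if cmp["selected"] == "inv_mm":
                wins += 1
        assert wins > n_seeds / 2


class TestBootstrap:
    def test_zero_noise_degenerate_intervals(self, wt_params):
        ads = generate_adsorption(wt_params, DEFAULT_ET_GRID["30C"], 500.0, cv=0.0, seed=0)
        X, y, sd = ads.to_Xy()
        est = AdsorptionIsotherm(n_starts=4, random_state=0).fit(X, y, y_sd=sd)
        ci = bootstrap_ci(est, X, y, y_sd=sd, n_boot=50, seed=0)
        for lo, hi in ci.values():
            assert hi - lo < 1e-4 * max(abs(lo), 1e-12)

    def test_deterministic_and_brackets_estimate(self, wt_params):
        E = (10.0, 40.0, 100.0, 300.0, 600.0)
        ads = generate_adsorption(wt_params, E, 500.0, cv=0.05, seed=1)
        X, y, sd = ads.to_Xy()
        est = AdsorptionIsotherm(n_starts=4, random_state=0).fit(X, y, y_sd=sd)
        ci1 = bootstrap_ci(est, X, y, y_sd=sd, n_boot=50, seed=5)
        ci2 = bootstrap_ci(est, X, y, y_sd=sd, n_boot=50, seed=5)
        assert ci1 == ci2
        assert ci1["K_a"][0] <= est.K_a_ <= ci1["K_a"][1]
        assert ci1["Gamma"][0] <= est.Gamma_ <= ci1["Gamma"][1]

    def test_small_n_boot_warns(self, wt_params):
        ads = generate_adsorption(wt_params, (10.0, 40.0, 100.0, 300.0, 600.0),
                                  500.0, cv=0.05, seed=1)
        X, y, sd = ads.to_Xy()
        est = AdsorptionIsotherm(n_starts=4, random_state=0).fit(X, y, y_sd=sd)
        with pytest.warns(UserWarning, match="small"):
            bootstrap_ci(est, X, y, y_sd=sd, n_boot=10, seed=0)


class TestInverseMMRegressor:
    def test_recovers_generating_parameters(self):
        truth = InvMMParameters(k_inv=0.5, Gamma_inv=0.1, K_inv=80.0)
        E = np.linspace(10, 600, 15)
        X = np.column_stack([E, np.full_like(E, 500.0)])
        y = inv_mm_rate_grid(truth, X[:, 0], X[:, 1])
        est = InverseMMRegressor(n_starts=16, random_state=0).fit(X, y)
        # k_inv and Gamma_inv only appear as a product: check product + K_inv
        prod = est.params_.k_inv * est.params_.Gamma_inv
        assert prod == pytest.approx(truth.k_inv * truth.Gamma_inv, rel=1e-4)
        assert est.params_.K_inv == pytest.approx(truth.K_inv, rel=1e-3)
        assert np.allclose(est.predict(X), y, rtol=1e-5)
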