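"""Two-flux fitting: cost function, optimizers, goodness of fit and
Monte Carlo uncertainty."""

import numpy as np
import pandas as pd
import pytest


from mitoflux.flux_fitting import (
    FitConfig,
    cost_function,
    fit_fluxes,
    goodness_of_fit,
    monte_carlo_errors,
    observations_from_timecourse,
)
from mitoflux.isotopomer_model import simulate_labeling

TOY_BOUNDS = {"F_cycle": (1e-3, 1.0), "F_exch": (1e-3, 1.0)}
TOY_TRUTH = {"F_cycle": 0.05, "F_exch": 0.03}


def toy_config(algorithm="bfgs", **kw):
    return FitConfig(free_params=dict(TOY_BOUNDS), algorithm=algorithm, **kw)


class TestCostFunction:
    def test_zero_at_generating_parameters(self, toy_system, toy_observations,
                                           toy_input):
        c = cost_function(TOY_TRUTH, toy_observations, toy_system, toy_input)
        assert c == pytest.approx(0.0, abs=1e-10)

    def test_doubling_sds_quarters_cost(self, toy_system, toy_observations,
                                        toy_input):
        params = {"F_cycle": 0.08, "F_exch": 0.02}
        c1 = cost_function(params, toy_observations, toy_system, toy_input)
        wide = toy_observations.copy()
        wide["sd"] = 2.0 * wide["sd"]
        c2 = cost_function(params, wide, toy_system, toy_input)
        assert c2 == pytest.approx(c1 / 4.0, rel=1e-9)

    def test_hand_computed_three_point_example(self, toy_system, toy_observations,
                                               toy_input):
        # residuals 0.01, -0.02, 0.03 with sd 0.01 -> sum (r/sd)^2 = 14
        obs = toy_observations.iloc[[1, 2, 3]].copy()
        pred_cost = cost_function(TOY_TRUTH, obs, toy_system, toy_input)
        assert pred_cost == pytest.approx(0.0, abs=1e-10)
        obs["fraction"] = obs["fraction"].to_numpy() + [0.01, -0.02, 0.03]
        obs["sd"] = 0.01
        assert cost_function(TOY_TRUTH, obs, toy_system, toy_input) == pytest.approx(
            14.0, rel=1e-6
        )

    def test_row_order_invariance(self, toy_system, toy_observations, toy_input):
        params = {"F_cycle": 0.07, "F_exch": 0.05}
        c1 = cost_function(params, toy_observations, toy_system, toy_input)
        shuffled = toy_observations.sample(frac=1.0, random_state=3)
        c2 = cost_function(params, shuffled, toy_system, toy_input)
        assert c2 == pytest.approx(c1, rel=1e-12)

    def test_empty_observations_rejected(self, toy_system):
        with pytest.raises(ValueError):
            cost_function(TOY_TRUTH, pd.DataFrame(), toy_system)


class TestFitFluxes:
    @pytest.mark.parametrize("algorithm", ["bfgs", "simplex"])
    def test_noiseless_recovery_multistart(self, toy_system, toy_observations,
                                           toy_input, algorithm):
        est = fit_fluxes(
            toy_observations, toy_system, toy_config(algorithm), input_fn=toy_input
        )
        assert est.converged
        assert est.params["F_cycle"] == pytest.approx(0.05, rel=1e-3)
        assert est.params["F_exch"] == pytest.approx(0.03, rel=1e-3)

    def test_recovery_across_flux_grid_both_optimizers(
        self, toy_system, toy_input, toy_t_grid
    ):
        # noiseless recovery over a grid spanning the physiological decade
        for f_cycle in (0.02, 0.06, 0.2):
            for f_exch in (0.01, 0.03, 0.1):
                tc = simulate_labeling(
                    toy_system,
                    fluxes={"F_cycle": f_cycle, "F_exch": f_exch},
                    input_fn=toy_input,
                    t_grid=toy_t_grid,
                )
                obs = observations_from_timecourse(tc, metabolite="obs", sd=0.01)
                for algorithm in ("bfgs", "simplex"):
                    est = fit_fluxes(
                        obs,
                        toy_system,
                        toy_config(algorithm),
                        input_fn=toy_input,
                        x0={"F_cycle": 0.5 * f_cycle, "F_exch": 2.0 * f_exch},
                    )
                    assert est.params["F_cycle"] == pytest.approx(f_cycle, rel=1e-3)
                    assert est.params["F_exch"] == pytest.approx(f_exch, rel=1e-3)

    def test_algorithms_agree(self, toy_system, toy_observations, toy_input):
        est_b = fit_fluxes(toy_observations, toy_system, toy_config("bfgs"),
                           input_fn=toy_input)
        est_s = fit_fluxes(toy_observations, toy_system, toy_config("simplex"),
                           input_fn=toy_input)
        for name in TOY_BOUNDS:
            assert est_b.params[name] == pytest.approx(est_s.params[name], rel=1e-3)

    def test_seed_independent_when_noiseless(self, toy_system, toy_observations,
                                             toy_input):
        e1 = fit_fluxes(toy_observations, toy_system, toy_config(seed=1),
                        input_fn=toy_input)
        e2 = fit_fluxes(toy_observations, toy_system, toy_config(seed=99),
                        input_fn=toy_input)
        assert e1.params == e2.params

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(algorithm="newton")
        with pytest.raises(ValueError):
            FitConfig(free_params={"F_TCA": (-1.0, 1.0)})


class TestGoodnessOfFit:
    def test_perfect_fit_flagged_suspicious(self, toy_system, toy_observations,
                                            toy_input):
        est = fit_fluxes(toy_observations, toy_system, toy_config(),
                         input_fn=toy_input)
        red, ok = goodness_of_fit(est)
        assert red == pytest.approx(0.0, abs=1e-8)
        assert not ok

    def test_reduced_chi2_distribution_under_correct_model(
        self, toy_system, fast_toy_observations, toy_input
    ):
        toy_observations = fast_toy_observations
        # correct model + nominal noise: mean reduced chi2 near 1
        rng = np.random.default_rng(0)
        sd = 0.01
        reds = []
        for _ in range(80):
            rep = toy_observations.copy()
            rep["fraction"] = rep["fraction"] + rng.normal(0.0, sd, len(rep))
            rep["sd"] = sd
            est = fit_fluxes(rep, toy_system, toy_config(), input_fn=toy_input,
                             x0=TOY_TRUTH, sim_rtol=1e-5, sim_atol=1e-8)
            red, _ = goodness_of_fit(est)
            reds.append(red)
        assert 0.8 <= np.mean(reds) <= 1.2

    def test_noise_doubling_scales_reduced_chi2(self, toy_system,
                                                toy_observations, toy_input):
        rng = np.random.default_rng(4)
        sd = 0.01
        rep = toy_observations.copy()
        rep["fraction"] = rep["fraction"] + rng.normal(0.0, 2 * sd, len(rep))
        rep["sd"] = sd  # weights kept at the nominal level
        est = fit_fluxes(rep, toy_system, toy_config(), input_fn=toy_input,
                         x0=TOY_TRUTH)
        red, _ = goodness_of_fit(est)
        assert 2.0 < red < 7.0  # ~4 with chi-square scatter at 12 dof

    def test_insufficient_dof_rejected(self, toy_system, toy_observations,
                                       toy_input):
        est = fit_fluxes(toy_observations, toy_system, toy_config(),
                         input_fn=toy_input)
        with pytest.raises(ValueError):
            goodness_of_fit(est, n_points=2, n_params=2)


class TestMonteCarloErrors:
    def test_zero_noise_zero_se(self, toy_system, fast_toy_observations, toy_input):
        est = monte_carlo_errors(
            fast_toy_observations, toy_system, toy_config(), noise_sd=0.0,
            n_reps=50, seed=0, input_fn=toy_input,
            sim_rtol=1e-5, sim_atol=1e-8,
        )
        assert est.mc_se["F_cycle"] == pytest.approx(0.0, abs=1e-10)
        assert est.mc_se["F_exch"] == pytest.approx(0.0, abs=1e-10)

    def test_se_scales_linearly_with_noise(self, toy_system, fast_toy_observations,
                                           toy_input):
        ses = []
        for sd in (0.005, 0.01):
            est = monte_carlo_errors(
                fast_toy_observations, toy_system, toy_config(), noise_sd=sd,
                n_reps=50, seed=2, input_fn=toy_input,
                sim_rtol=1e-5, sim_atol=1e-8,
            )
            ses.append(est.mc_se["F_cycle"])
        ratio = ses[1] / ses[0]
        assert 1.5 < ratio < 2.6

    def test_ci_coverage_in_nested_study(self, toy_system, toy_input,
                                         fast_t_grid):
        # scaled-down nested study: 12 outer replicates, 50 inner refits
        sd = 0.01
        tc = simulate_labeling(
            toy_system, fluxes=TOY_TRUTH, input_fn=toy_input, t_grid=fast_t_grid
        )
        clean = observations_from_timecourse(tc, metabolite="obs", sd=sd)
        rng = np.random.default_rng(0)
        covered = 0
        n_outer = 12
        for k in range(n_outer):
            noisy = clean.copy()
            noisy["fraction"] = clean["fraction"] + rng.normal(0.0, sd, len(clean))
            est = fit_fluxes(noisy, toy_system, toy_config(), input_fn=toy_input,
                             x0=TOY_TRUTH, sim_rtol=1e-5, sim_atol=1e-8)
            est = monte_carlo_errors(
                noisy, toy_system, toy_config(), noise_sd=sd, n_reps=50,
                seed=1000 + k, input_fn=toy_input, estimate=est,
                sim_rtol=1e-5, sim_atol=1e-8,
            )
            lo, hi = est.mc_ci95["F_cycle"]
            covered += lo <= TOY_TRUTH["F_cycle"] <= hi
        assert covered / n_outer >= 0.8

    def test_too_few_reps_rejected(self, toy_system, toy_observations, toy_input):
        with pytest.raises(ValueError):
            monte_carlo_errors(
                toy_observations, toy_system, toy_config(), noise_sd=0.01,
                n_reps=10, input_fn=toy_input,
            )
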