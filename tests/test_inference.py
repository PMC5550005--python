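"""Posterior composition, MCMC sampling and predictive replication."""

import numpy as np
import pytest
from scipy.special import xlog1py, xlogy

from cryptdrift.discrete import solve_master_equation
from cryptdrift.inference import (FitConfig, ForwardModel, log_posterior,
                                  predictive_sample, run_mcmc)
from cryptdrift.measurement import (CountData, SpaceTimeGrid,
                                    fit_reference_spline)
from cryptdrift.priors import (PriorSpec, RegionMap, build_covariance,
                               expand_to_grid, prior_logpdf)
from cryptdrift.synthetic import DEFAULT_K_STAR, ScenarioSpec, generate_dataset


def _toy_data(rng, n_cells=12, times=(0.0, 200.0), n=40):
    grid = SpaceTimeGrid(n_cells=n_cells, times=np.array(times))
    L = np.clip(np.linspace(0.9, 0.05, n_cells), 0, 1)
    narr = np.full((len(times), n_cells), n)
    y = rng.binomial(narr, L[None, :])
    return CountData(grid=grid, n=narr, y=y)


class TestLogPosterior:
    def test_prior_only_maximised_at_mu(self, rng):
        """With no fitted times the target is the prior alone, peaked at mu."""
        data = _toy_data(rng)
        spec = PriorSpec(m=3, mu=np.array([1e-3, 2e-3, 1e-3]),
                         sigma=np.full(3, 5e-4), lc=1.0)
        rmap = RegionMap(bounds=np.array([0.0, 4.0, 8.0, 12.0]))
        cfg = FitConfig(init_time=0.0, fit_times=())
        at_mu = log_posterior(spec.mu, data, spec, cfg, rmap)
        for _ in range(20):
            k = spec.mu + rng.normal(0, 5e-4, 3)
            assert log_posterior(k, data, spec, cfg, rmap) <= at_mu + 1e-12

    def test_composition_matches_hand_built_oracle(self, rng):
        """3-region toy, master-equation link: prior + binomial pieces composed
        independently of the ForwardModel plumbing."""
        data = _toy_data(rng, n_cells=12, times=(0.0, 150.0))
        spec = PriorSpec(m=3, mu=np.full(3, 2e-3), sigma=np.full(3, 1e-3), lc=1.0)
        rmap = RegionMap(bounds=np.array([0.0, 4.0, 8.0, 12.0]),
                         zero_beyond_end=True)
        cfg = FitConfig(init_time=0.0, fit_times=(150.0,),
                        process_model="master_equation", clip_eps=1e-9)
        k = np.array([1e-3, 3e-3, 5e-4])
        got = log_posterior(k, data, spec, cfg, rmap)
        # oracle: spline IC -> master equation -> clipped binomial kernel
        spl = fit_reference_spline(data, 0.0)
        k_fine, _ = expand_to_grid(k, rmap, 12)
        L = solve_master_equation(spl.fitted, k_fine, [150.0])[0]
        L = np.clip(L, 1e-9, 1 - 1e-9)
        j = data.grid.time_index(150.0)
        ll = float(np.sum(xlogy(data.y[j], L) + xlog1py(data.n[j] - data.y[j], -L)))
        assert got == pytest.approx(prior_logpdf(k, spec) + ll, rel=1e-10)

    def test_saturated_likelihood_value(self, rng):
        """L == observed fractions gives the saturated binomial kernel value."""
        data = _toy_data(rng)
        rmap = RegionMap(bounds=np.array([0.0, 6.0, 12.0]))
        cfg = FitConfig(init_time=0.0, fit_times=(200.0,))
        fwd = ForwardModel(data, rmap, cfg)
        j = data.grid.time_index(200.0)
        frac = data.y[j] / data.n[j]
        sat = float(np.sum(xlogy(data.y[j], frac) +
                           xlog1py(data.n[j] - data.y[j], -frac)))
        got = fwd.loglik(frac[None, :])
        assert got == pytest.approx(sat, abs=1e-6)

    def test_forward_map_bit_stable(self, healthy_truth, healthy_forward, true_k):
        a = healthy_forward(true_k)
        b = healthy_forward(true_k)
        assert np.array_equal(a, b)


class TestRunMcmc:
    def test_gaussian_target_moments(self, rng):
        """Sampler correctness: prior-only target reproduces (mu, C) at m=5."""
        data = _toy_data(rng, n_cells=30)
        spec = PriorSpec()
        rmap = RegionMap.equal_regions(m=5, crypt_end=30.0)
        cfg = FitConfig(init_time=0.0, fit_times=(), n_walkers=32,
                        n_steps=1500, burn_in=500, seed=7)
        post = run_mcmc(data, spec, cfg, rmap)
        C = build_covariance(spec)
        n_eff = 300  # conservative: heavy walker autocorrelation
        for d in range(5):
            se = np.sqrt(C[d, d] / n_eff)
            assert abs(post.mean()[d] - spec.mu[d]) < 4 * se
        C_hat = np.cov(post.draws.T)
        assert np.linalg.norm(C_hat - C) / np.linalg.norm(C) < 0.25

    def test_walker_floor(self, rng):
        data = _toy_data(rng)
        spec = PriorSpec()
        with pytest.raises(ValueError, match="walkers"):
            run_mcmc(data, spec, FitConfig(init_time=0.0, fit_times=(200.0,),
                                           n_walkers=6, n_steps=50, burn_in=10))

    def test_seed_stability(self, healthy_truth, prior_spec, region_map):
        """Two chains with different seeds agree within Monte-Carlo error."""
        means = []
        ses = []
        for seed in (101, 202):
            cfg = FitConfig(init_time=120.0, fit_times=(360.0, 600.0),
                            n_walkers=32, n_steps=700, burn_in=300, seed=seed)
            post = run_mcmc(healthy_truth.data, prior_spec, cfg, region_map)
            means.append(post.mean())
            n_eff = 250
            ses.append(post.draws.std(axis=0) / np.sqrt(n_eff))
        combined = np.sqrt(ses[0] ** 2 + ses[1] ** 2)
        assert np.all(np.abs(means[0] - means[1]) < 3 * combined)

    def test_interval_width_shrinks_with_more_data(self, healthy_truth, prior_spec,
                                                   region_map):
        """Fitting two times constrains the rates at least as tightly as one."""
        widths = {}
        for tag, fit_times in (("one", (360.0,)), ("two", (360.0, 600.0))):
            cfg = FitConfig(init_time=120.0, fit_times=fit_times,
                            n_walkers=32, n_steps=700, burn_in=300, seed=55)
            post = run_mcmc(healthy_truth.data, prior_spec, cfg, region_map)
            lo, hi = post.credible_interval(0.95)
            widths[tag] = hi - lo
        assert np.mean(widths["two"]) <= 1.1 * np.mean(widths["one"])

    def test_treatment_tag_never_branches_the_model(self, healthy_truth,
                                                    prior_spec, region_map):
        """Identical seeds with different condition labels give identical draws."""
        draws = []
        for condition in ("healthy", "blocked"):
            cfg = FitConfig(init_time=120.0, fit_times=(360.0,), n_walkers=16,
                            n_steps=120, burn_in=40, seed=9, condition=condition)
            post = run_mcmc(healthy_truth.data, prior_spec, cfg, region_map)
            draws.append(post.draws)
        assert np.array_equal(draws[0], draws[1])

    def test_diagnostics_reported(self, healthy_posterior):
        assert 0.05 < healthy_posterior.acceptance_fraction < 0.95
        assert healthy_posterior.rhat.shape == (5,)
        assert np.all(healthy_posterior.rhat < 1.3)
        assert np.all(np.isfinite(healthy_posterior.log_post))


class TestPredictiveSample:
    def test_zero_sample_sizes_give_zero_counts(self, rng):
        data = _toy_data(rng)
        data.n[:] = 0
        data.y[:] = 0
        grid = data.grid
        # spline needs observed sites at the init time: restore the first row
        data.n[0] = 40
        cfg = FitConfig(init_time=0.0, fit_times=(200.0,))
        rmap = RegionMap(bounds=np.array([0.0, 6.0, 12.0]))
        fwd = ForwardModel(data, rmap, cfg)
        reps = predictive_sample(np.full((1, 2), 1e-3), data, cfg, 5, seed=3,
                                 forward=fwd)
        assert np.all(reps.ys[:, 1] == 0)

    def test_replicate_variance_matches_binomial(self, rng):
        """Fixed k: across replicates Var(y) ~= n L (1 - L) sitewise."""
        data = _toy_data(rng, n=100)
        cfg = FitConfig(init_time=0.0, fit_times=(200.0,))
        rmap = RegionMap(bounds=np.array([0.0, 6.0, 12.0]))
        fwd = ForwardModel(data, rmap, cfg)
        k = np.full((1, 2), 1.5e-3)
        reps = predictive_sample(k, data, cfg, 4000, seed=10, forward=fwd)
        L = reps.Ls[0, 1]
        expected_var = 100 * L * (1 - L)
        observed_var = reps.ys[:, 1, :].var(axis=0)
        m = expected_var > 1.0
        assert np.allclose(observed_var[m], expected_var[m], rtol=0.25)

    def test_empty_draws_rejected(self, rng):
        data = _toy_data(rng)
        cfg = FitConfig(init_time=0.0, fit_times=(200.0,))
        with pytest.raises(ValueError, match="nonempty"):
            predictive_sample(np.empty((0, 2)), data, cfg, 3, seed=0)

    def test_posterior_predictive_calibrated(self, healthy_truth,
                                             healthy_replicates):
        """>= 90% of observed counts inside central 95% predictive intervals."""
        data = healthy_truth.data
        ys = healthy_replicates.ys
        hits = total = 0
        for j, t in enumerate(data.grid.times):
            if t == 120.0:
                continue
            lo = np.quantile(ys[:, j, :], 0.025, axis=0)
            hi = np.quantile(ys[:, j, :], 0.975, axis=0)
            m = data.n[j] > 0
            hits += int(np.sum((data.y[j][m] >= lo[m]) & (data.y[j][m] <= hi[m])))
            total += int(np.sum(m))
        assert hits / total >= 0.90
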