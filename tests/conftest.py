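"""Shared fixtures: small count datasets and session-scoped posterior fits.

The MCMC fits are expensive, so the healthy / blocked / circadian fits are
computed once per session and shared between the inference, checking and
acceptance tests.  All seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from cryptdrift.inference import FitConfig, ForwardModel, predictive_sample, run_mcmc
from cryptdrift.measurement import CountData, SpaceTimeGrid
from cryptdrift.priors import PriorSpec, RegionMap
from cryptdrift.synthetic import DEFAULT_K_STAR, ScenarioSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_data():
    """Tiny 5-site, 2-time count dataset with hand-set values."""
    grid = SpaceTimeGrid(n_cells=5, times=np.array([0.0, 100.0]))
    n = np.array([[10, 10, 10, 10, 10], [8, 8, 8, 8, 8]])
    y = np.array([[9, 7, 5, 2, 0], [7, 6, 5, 3, 1]])
    return CountData(grid=grid, n=n, y=y)


@pytest.fixture(scope="session")
def region_map():
    return RegionMap.equal_regions()


@pytest.fixture(scope="session")
def prior_spec():
    return PriorSpec()


@pytest.fixture(scope="session")
def healthy_truth():
    return generate_dataset(ScenarioSpec(condition="healthy", seed=20260901),
                            variant="advection")


@pytest.fixture(scope="session")
def healthy_fit_config():
    return FitConfig(init_time=120.0, fit_times=(360.0, 600.0),
                     n_walkers=32, n_steps=2000, burn_in=500, seed=41)


@pytest.fixture(scope="session")
def healthy_posterior(healthy_truth, prior_spec, healthy_fit_config, region_map):
    return run_mcmc(healthy_truth.data, prior_spec, healthy_fit_config, region_map)


@pytest.fixture(scope="session")
def healthy_forward(healthy_truth, healthy_fit_config, region_map):
    return ForwardModel(healthy_truth.data, region_map, healthy_fit_config)


@pytest.fixture(scope="session")
def healthy_replicates(healthy_posterior, healthy_truth, healthy_fit_config,
                       healthy_forward):
    return predictive_sample(healthy_posterior.draws, healthy_truth.data,
                             healthy_fit_config, n_reps=60, seed=77,
                             forward=healthy_forward)


@pytest.fixture(scope="session")
def blocked_truth():
    """Blocked condition, spline-realisable latent truth (calibration variant)."""
    from cryptdrift.workflows import well_specified_dataset
    return well_specified_dataset(ScenarioSpec(condition="blocked", seed=20260902))


@pytest.fixture(scope="session")
def blocked_posterior(blocked_truth, prior_spec, region_map):
    cfg = FitConfig(init_time=1140.0, fit_times=(1500.0,),
                    n_walkers=32, n_steps=2000, burn_in=600, seed=42)
    return run_mcmc(blocked_truth.data, prior_spec, cfg, region_map)


@pytest.fixture(scope="session")
def circadian_truth():
    """Healthy scenario with 20% circadian rate modulation (period 24 h)."""
    return generate_dataset(
        ScenarioSpec(condition="healthy", time_variation=(0.2, 1440.0),
                     seed=20260903),
        variant="advection")


@pytest.fixture(scope="session")
def circadian_posterior(circadian_truth, prior_spec, region_map):
    cfg = FitConfig(init_time=120.0, fit_times=(360.0, 600.0),
                    n_walkers=32, n_steps=800, burn_in=300, seed=43)
    return run_mcmc(circadian_truth.data, prior_spec, cfg, region_map)


@pytest.fixture(scope="session")
def true_k():
    return DEFAULT_K_STAR.copy()
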