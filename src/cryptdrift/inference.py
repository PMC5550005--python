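"""Posterior composition and MCMC over the region proliferation rates.

The hierarchical factorisation p(y, L, k | n, E) = p(y | L, n) p(L | k) p(k | E)
with a deterministic process link L = f(k) collapses to the unnormalised
posterior

    log p(k | y) = log p(k) + sum_{fitted times} log p(y_t | f(k)_t, n_t),

where f(k) is computed by (i) holding the smoothing-spline fit of the
initial-condition time fixed as L(., t0), (ii) expanding k from the m coarse
regions to the cell grid and (iii) running the configured forward solver to
each fitted time.  The treatment condition enters only through k and its prior;
measurement and process code paths are identical across conditions.

Sampling uses the affine-invariant ensemble sampler (emcee), walkers
initialised from the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import emcee
import numpy as np

from .continuum import solve_advection, solve_fokker_planck, velocity_from_rates
from .discrete import solve_master_equation
from .measurement import (CountData, SplineProfile, fit_reference_spline)
from .priors import PriorSpec, RegionMap, expand_to_grid, prior_logpdf, sample_prior

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "ReplicatedDataset",
    "ForwardModel",
    "log_posterior",
    "run_mcmc",
    "predictive_sample",
    "split_rhat",
]

_PROCESS_MODELS = ("advection", "fokker_planck", "master_equation")
_LIKELIHOODS = ("binomial", "gaussian_approx")


@dataclass
class FitConfig:
    """Controls for one posterior fit (times in minutes)."""

    init_time: float
    fit_times: tuple
    process_model: str = "advection"
    likelihood: str = "binomial"
    n_walkers: int = 32
    n_steps: int = 2000
    burn_in: int = 500
    seed: int = 0
    condition: str = "healthy"   # metadata only: never branches the model
    refine: int = 2
    cfl: float = 0.9
    spline_smoothing: float | None = None
    clip_eps: float = 1e-9       # likelihood floor keeping log p finite off-support

    def __post_init__(self) -> None:
        self.fit_times = tuple(float(t) for t in self.fit_times)
        # an empty fit_times list targets the prior alone (sampler checks)
        if self.fit_times and min(self.fit_times) <= self.init_time:
            raise ValueError("fitted times must be strictly after the initial-condition time")
        if self.process_model not in _PROCESS_MODELS:
            raise ValueError(f"process_model must be one of {_PROCESS_MODELS}")
        if self.likelihood not in _LIKELIHOODS:
            raise ValueError(f"likelihood must be one of {_LIKELIHOODS}")
        if self.n_steps <= self.burn_in:
            raise ValueError("n_steps must exceed burn_in")


class ForwardModel:
    """Deterministic link L = f(k): spline initial condition + process solver.

    Precomputes everything reusable across posterior evaluations (spline fit of
    the initial time, count slices at the fitted times) so a call costs one
    forward solve.  f is bit-stable for fixed k and configuration.
    """

    def __init__(self, data: CountData, region_map: RegionMap, cfg: FitConfig):
        self.data = data
        self.region_map = region_map
        self.cfg = cfg
        self.n_cells = data.grid.n_cells
        self.spline: SplineProfile = fit_reference_spline(data, cfg.init_time,
                                                          cfg.spline_smoothing)
        self._fit_idx = [data.grid.time_index(t) for t in cfg.fit_times]
        self.n_fit = data.n[self._fit_idx]
        self.y_fit = data.y[self._fit_idx]
        self._mask = self.n_fit > 0
        # initial states for each solver family
        self._p0_sites = self.spline.fitted.copy()
        dx = 1.0 / cfg.refine
        self._x_fine = np.arange(0.0, self.n_cells - 1 + 0.5 * dx, dx)
        self._L0_fine = np.clip(self.spline(self._x_fine), 0.0, 1.0)

    def predict(self, k_regions: np.ndarray, times, process_model: str | None = None,
                scale: float = 1.0) -> np.ndarray:
        """Latent fractions at the sites for arbitrary requested times (>= t0)."""
        model = process_model or self.cfg.process_model
        k = scale * np.asarray(k_regions, dtype=float)
        k_fine, k_fn = expand_to_grid(k, self.region_map, self.n_cells)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if model == "master_equation":
            return solve_master_equation(self._p0_sites, k_fine, times,
                                         t0=self.cfg.init_time)
        v = velocity_from_rates(k_fn)
        if model == "advection":
            sol = solve_advection(self._L0_fine, v, times, t0=self.cfg.init_time,
                                  domain_end=float(self.n_cells - 1),
                                  refine=self.cfg.refine, cfl=self.cfg.cfl)
        else:
            sol = solve_fokker_planck(self._L0_fine, v, 1.0, times,
                                      t0=self.cfg.init_time,
                                      domain_end=float(self.n_cells - 1),
                                      refine=self.cfg.refine, cfl=self.cfg.cfl)
        return sol.on_sites(self.n_cells)

    def __call__(self, k_regions: np.ndarray) -> np.ndarray:
        """L at the fitted times, shape (len(fit_times), n_cells)."""
        if not self.cfg.fit_times:
            return np.empty((0, self.n_cells))
        return self.predict(k_regions, self.cfg.fit_times)

    def loglik(self, L_fit: np.ndarray) -> float:
        """Measurement log-likelihood of the fitted counts under latent L.

        The binomial form is coefficient-free (constant in k).  L is floored
        into [eps, 1-eps] so that proposals whose front misses observed label
        are strongly penalised yet finite; the gaussian_approx option uses the
        same floor to keep its variance positive.
        """
        eps = self.cfg.clip_eps
        L = np.clip(L_fit[self._mask], eps, 1.0 - eps)
        y = self.y_fit[self._mask]
        n = self.n_fit[self._mask]
        if self.cfg.likelihood == "binomial":
            return float(np.sum(y * np.log(L) + (n - y) * np.log1p(-L)))
        var = L * (1.0 - L) / n
        resid = y / n - L
        return float(np.sum(-0.5 * np.log(2.0 * np.pi * var) - resid**2 / (2.0 * var)))


def log_posterior(k: np.ndarray, data: CountData, spec: PriorSpec, cfg: FitConfig,
                  region_map: RegionMap | None = None,
                  forward: ForwardModel | None = None) -> float:
    """log p(k) + log p(y_fit | f(k)); -inf on forward-solver failure."""
    if forward is None:
        forward = ForwardModel(data, region_map or RegionMap.equal_regions(m=spec.m),
                               cfg)
    lp = prior_logpdf(k, spec)
    if not np.isfinite(lp):
        return -np.inf
    try:
        L = forward(k)
    except Exception as exc:  # solver failure == rejected proposal
        logger.warning("forward solver failed at k=%s: %s", k, exc)
        return -np.inf
    ll = forward.loglik(L)
    return lp + ll if np.isfinite(ll) else -np.inf


def split_rhat(chain: np.ndarray) -> float:
    """Split-R-hat of one scalar chain array (n_steps, n_walkers)."""
    n, w = chain.shape
    half = n // 2
    segs = np.concatenate([chain[:half], chain[half: 2 * half]], axis=1)  # (half, 2w)
    mean_c = segs.mean(axis=0)
    var_c = segs.var(axis=0, ddof=1)
    W = var_c.mean()
    B = half * mean_c.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W)) if W > 0 else np.inf


@dataclass
class PosteriorSamples:
    """Kept MCMC draws of k plus sampling diagnostics."""

    draws: np.ndarray         # (n_kept, m)
    log_post: np.ndarray      # (n_kept,)
    acceptance_fraction: float
    rhat: np.ndarray          # (m,)
    config: FitConfig
    chain_shape: tuple        # (kept steps, walkers, m)

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = 0.5 * (1.0 - level)
        lo = np.quantile(self.draws, a, axis=0)
        hi = np.quantile(self.draws, 1.0 - a, axis=0)
        return lo, hi


def _init_walkers(spec: PriorSpec, cfg: FitConfig, target, rng) -> np.ndarray:
    """Prior draws with non-finite-posterior redraws (capped)."""
    out = np.empty((cfg.n_walkers, spec.m))
    filled = 0
    tries = 0
    cap = 200 * cfg.n_walkers
    while filled < cfg.n_walkers:
        if tries >= cap:
            raise RuntimeError(
                "could not find enough prior draws with finite posterior; "
                "check data/solver configuration")
        k = sample_prior(spec, 1, rng.integers(2**31))[0]
        tries += 1
        if np.isfinite(target(k)):
            out[filled] = k
            filled += 1
    return out


def run_mcmc(data: CountData, spec: PriorSpec, cfg: FitConfig,
             region_map: RegionMap | None = None) -> PosteriorSamples:
    """Affine-invariant ensemble sampling of the posterior over k.

    Walkers start from prior draws (non-finite posteriors redrawn); the first
    ``burn_in`` steps are discarded.  Reports the mean acceptance fraction and
    split-R-hat per component; raises if the ensemble is essentially stuck.
    Reproducible under ``cfg.seed``.
    """
    if cfg.n_walkers < 2 * spec.m:
        raise ValueError("need at least 2*m walkers")
    region_map = region_map or RegionMap.equal_regions(m=spec.m)
    forward = ForwardModel(data, region_map, cfg)

    def target(k):
        return log_posterior(k, data, spec, cfg, region_map, forward)

    rng = np.random.default_rng(cfg.seed)
    p0 = _init_walkers(spec, cfg, target, rng)
    # Stage 1: short pilot from the prior draws locates the posterior bulk.
    # Stage 2: all walkers restart in a small ball around the best pilot point,
    # avoiding the stuck-walker pathology of stretch moves when part of the
    # ensemble is initialised far into the likelihood tail.
    pilot = emcee.EnsembleSampler(cfg.n_walkers, spec.m, target)
    pilot._random = np.random.RandomState(rng.integers(2**31))
    n_pilot = min(200, max(50, cfg.n_steps // 10))
    pilot.run_mcmc(p0, n_pilot, progress=False)
    flat = pilot.get_chain(flat=True)
    best = flat[np.argmax(pilot.get_log_prob(flat=True))]
    scale = 0.02 * np.where(spec.sigma > 0, spec.sigma, np.max(spec.sigma) + 1e-12)
    p1 = best[None, :] + scale[None, :] * rng.standard_normal((cfg.n_walkers, spec.m))
    sampler = emcee.EnsembleSampler(cfg.n_walkers, spec.m, target)
    sampler._random = np.random.RandomState(rng.integers(2**31))
    sampler.run_mcmc(p1, cfg.n_steps, progress=False)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < 0.01:
        raise RuntimeError(
            f"ensemble stuck (acceptance {acc:.3%}); consider reparameterising "
            "or widening the prior")
    chain = sampler.get_chain(discard=cfg.burn_in)      # (kept, walkers, m)
    logp = sampler.get_log_prob(discard=cfg.burn_in)
    rhat = np.array([split_rhat(chain[:, :, d]) for d in range(spec.m)])
    draws = chain.reshape(-1, spec.m)
    return PosteriorSamples(draws=draws, log_post=logp.reshape(-1),
                            acceptance_fraction=acc, rhat=rhat, config=cfg,
                            chain_shape=chain.shape)


@dataclass
class ReplicatedDataset:
    """Predictive replicates: counts and their own latent fields per draw."""

    ys: np.ndarray        # (n_reps, n_times, n_cells)
    Ls: np.ndarray        # (n_reps, n_times, n_cells)
    ks: np.ndarray        # (n_reps, m)
    times: np.ndarray
    template: CountData
    provenance: str       # "prior" | "posterior"
    seed: int


def predictive_sample(k_draws: np.ndarray, template: CountData, cfg: FitConfig,
                      n_reps: int, seed, region_map: RegionMap | None = None,
                      forward: ForwardModel | None = None,
                      provenance: str = "posterior") -> ReplicatedDataset:
    """Draw replicated datasets y ~ p(y | f(k)) with one k per replicate.

    ``k_draws`` may come from the prior (prior predictive) or an MCMC run
    (posterior predictive).  Replicates carry the template's sample sizes; at
    the initial-condition time the latent field is the (fixed) spline itself.
    """
    k_draws = np.atleast_2d(np.asarray(k_draws, dtype=float))
    if k_draws.size == 0:
        raise ValueError("k_draws must be nonempty")
    rng = np.random.default_rng(seed)
    if forward is None:
        forward = ForwardModel(template, region_map or RegionMap.equal_regions(),
                               cfg)
    times = template.grid.times
    later = times[times > cfg.init_time]
    n_times, n_cells = template.n.shape
    ys = np.empty((n_reps, n_times, n_cells), dtype=np.int64)
    Ls = np.empty((n_reps, n_times, n_cells))
    ks = np.empty((n_reps, k_draws.shape[1]))
    init_row = template.grid.time_index(cfg.init_time)
    for r in range(n_reps):
        k = k_draws[rng.integers(len(k_draws))]
        ks[r] = k
        L = np.empty((n_times, n_cells))
        L[init_row] = forward.spline.fitted
        if later.size:
            L_later = forward.predict(k, later)
            for j, t in enumerate(later):
                L[template.grid.time_index(t)] = L_later[j]
        L = np.clip(L, 0.0, 1.0)
        Ls[r] = L
        ys[r] = rng.binomial(template.n, L)
    seed_echo = int(seed) if isinstance(seed, (int, np.integer)) else -1
    return ReplicatedDataset(ys=ys, Ls=Ls, ks=ks, times=times, template=template,
                             provenance=provenance, seed=seed_echo)
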