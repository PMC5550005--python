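"""Run configuration: YAML files with validated sections, merged over defaults.

Sections (all optional in a file; unknown keys are rejected):

    grid:    n_cells, crypt_end
    regions: m, bounds, zero_beyond_end
    prior:   mu, sigma, lc, jitter, mean_peak_region, mean_decay, mean_peak_value
    solver:  process_model, refine, cfl
    mcmc:    walkers, steps, burn_in, likelihood
    synth:   condition, scale, k_star, bump_centre, bump_width, bump_height,
             times, n_per_site, circadian_amplitude, circadian_period
    check:   reduction, coarse_time_bins, coarse_space_bins, n_replicates
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .inference import FitConfig
from .priors import PriorSpec, RegionMap, default_mean_trend
from .synthetic import DEFAULT_K_STAR, ScenarioSpec

__all__ = ["RunConfig", "default_config", "load_config"]

_SCHEMA = {
    "grid": {"n_cells", "crypt_end"},
    "regions": {"m", "bounds", "zero_beyond_end"},
    "prior": {"mu", "sigma", "lc", "jitter", "mean_peak_region", "mean_decay",
              "mean_peak_value"},
    "solver": {"process_model", "refine", "cfl"},
    "mcmc": {"walkers", "steps", "burn_in", "likelihood"},
    "synth": {"condition", "scale", "k_star", "bump_centre", "bump_width",
              "bump_height", "times", "n_per_site", "circadian_amplitude",
              "circadian_period"},
    "check": {"reduction", "coarse_time_bins", "coarse_space_bins", "n_replicates"},
}


def default_config() -> dict:
    return {
        "grid": {"n_cells": 60, "crypt_end": 30.0},
        "regions": {"m": 5, "bounds": None, "zero_beyond_end": True},
        "prior": {"mu": None, "sigma": 2e-3, "lc": 1.0, "jitter": 1e-12,
                  "mean_peak_region": 3, "mean_decay": 0.5,
                  "mean_peak_value": 2e-3},
        "solver": {"process_model": "advection", "refine": 2, "cfl": 0.9},
        "mcmc": {"walkers": 32, "steps": 2000, "burn_in": 500,
                 "likelihood": "binomial"},
        "synth": {"condition": "healthy", "scale": None, "k_star": None,
                  "bump_centre": 12.0, "bump_width": 36.0, "bump_height": 0.8,
                  "times": None, "n_per_site": 30,
                  "circadian_amplitude": 0.0, "circadian_period": 1440.0},
        "check": {"reduction": 0.2, "coarse_time_bins": 4,
                  "coarse_space_bins": 6, "n_replicates": 50},
    }


def _validate(tree: dict, path: str = "") -> None:
    for section, content in tree.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in section {section!r}")


@dataclass
class RunConfig:
    """Merged configuration tree plus provenance."""

    tree: dict
    source: str = "<defaults>"

    def section(self, name: str) -> dict:
        return self.tree[name]

    def region_map(self) -> RegionMap:
        r = self.tree["regions"]
        g = self.tree["grid"]
        if r["bounds"] is not None:
            return RegionMap(bounds=np.asarray(r["bounds"], dtype=float),
                             zero_beyond_end=bool(r["zero_beyond_end"]))
        return RegionMap.equal_regions(m=int(r["m"]), crypt_end=float(g["crypt_end"]),
                                       zero_beyond_end=bool(r["zero_beyond_end"]))

    def prior_spec(self) -> PriorSpec:
        p = self.tree["prior"]
        m = self.region_map().m
        mu = (np.asarray(p["mu"], dtype=float) if p["mu"] is not None
              else default_mean_trend(m, int(p["mean_peak_region"]),
                                      float(p["mean_decay"]),
                                      float(p["mean_peak_value"])))
        sigma = np.asarray(p["sigma"], dtype=float)
        if sigma.ndim == 0:
            sigma = np.full(m, float(sigma))
        return PriorSpec(m=m, mu=mu, sigma=sigma, lc=float(p["lc"]),
                         jitter=float(p["jitter"]))

    def scenario(self, seed: int) -> ScenarioSpec:
        s = self.tree["synth"]
        tv = None
        if s["circadian_amplitude"]:
            tv = (float(s["circadian_amplitude"]), float(s["circadian_period"]))
        k_star = (np.asarray(s["k_star"], dtype=float) if s["k_star"] is not None
                  else DEFAULT_K_STAR.copy())
        return ScenarioSpec(
            condition=s["condition"], k_star=k_star, scale=s["scale"],
            bump_centre=float(s["bump_centre"]), bump_width=float(s["bump_width"]),
            bump_height=float(s["bump_height"]),
            times=s["times"], n_per_site=int(s["n_per_site"]),
            time_variation=tv, seed=int(seed),
            n_cells=int(self.tree["grid"]["n_cells"]),
            region_map=self.region_map())

    def fit_config(self, init_time: float, fit_times, seed: int, **overrides) -> FitConfig:
        sv, mc = self.tree["solver"], self.tree["mcmc"]
        kw = dict(init_time=float(init_time), fit_times=tuple(fit_times),
                  process_model=sv["process_model"], likelihood=mc["likelihood"],
                  n_walkers=int(mc["walkers"]), n_steps=int(mc["steps"]),
                  burn_in=int(mc["burn_in"]), seed=int(seed),
                  refine=int(sv["refine"]), cfl=float(sv["cfl"]))
        kw.update(overrides)
        return FitConfig(**kw)


def load_config(path=None) -> RunConfig:
    """Defaults merged with an optional YAML file (file keys win)."""
    tree = default_config()
    source = "<defaults>"
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        _validate(user)
        for section, content in user.items():
            if content:
                tree[section].update(content)
        source = str(Path(path))
    _validate(tree)
    return RunConfig(tree=copy.deepcopy(tree), source=source)
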