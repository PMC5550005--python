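"""Model checking: residual decomposition, ECDF comparison, characteristic plane.

The hierarchical structure lets measurement- and process-level adequacy be
checked separately:

* measurement residuals  r = y/n - spline(x)    (data against its own smooth),
  compared with replicated residuals y_rep/n - L_rep from predictive draws --
  if the binomial measurement model is adequate, the two residual populations
  are exchangeable at every time;
* process residuals      L_model - spline(x)    -- systematic differences
  between the latent process prediction and the smoothed data flag process
  error (e.g. a too-fast front at a late, unfitted time).

Interpreting the fraction-scale residuals as measurement noise leans on the
normal approximation to the binomial; they are reported together with the
per-time noise scale (mean binomial standard error over observed sites) and
documented as approximate.  ECDF comparisons use the two-sample
Kolmogorov-Smirnov sup distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .inference import ForwardModel, PosteriorSamples, ReplicatedDataset
from .measurement import CountData, SplineProfile

__all__ = [
    "ResidualReport",
    "MisfitExperiment",
    "residual_decomposition",
    "ecdf_compare",
    "ecdf_null_distances",
    "noise_scale",
    "characteristic_plane",
    "misfit_experiment",
]


def noise_scale(data: CountData, spline: SplineProfile, time: float) -> float:
    """Per-time measurement-noise scale: mean binomial SE over observed sites.

    nu_t = mean_i sqrt(L~_i (1 - L~_i) / n_i) with L~ the spline profile --
    a single scalar summarising how large a fraction-scale residual ordinary
    sampling noise can produce at that time.
    """
    j = data.grid.time_index(time)
    m = data.n[j] > 0
    Ls = spline.fitted[m]
    return float(np.mean(np.sqrt(Ls * (1.0 - Ls) / data.n[j][m])))


def ecdf_compare(observed_residuals, replicated_residuals) -> float:
    """Two-sample Kolmogorov-Smirnov sup distance between residual ECDFs."""
    a = np.ravel(np.asarray(observed_residuals, dtype=float))
    b = np.ravel(np.asarray(replicated_residuals, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("residual sets must be nonempty")
    return float(ks_2samp(a, b, method="asymp").statistic)


def ecdf_null_distances(rep_y: np.ndarray, rep_L: np.ndarray, n: np.ndarray,
                        sites: np.ndarray, rep_resid: np.ndarray,
                        smoothing: float | None = None) -> np.ndarray:
    """Null distribution of the observed-vs-replicated ECDF distance.

    The observed residual subtracts a spline fitted to the data, while
    replicated residuals subtract each replicate's own latent field; the two
    procedures have different distributions even under a perfect model (the
    spline absorbs part of the noise).  The null therefore treats each
    replicate in turn as pseudo-data -- refitting a spline to its counts and
    subtracting it -- and measures the distance to the pool of the remaining
    replicates' latent-subtracted residuals.

    Parameters: per-time slices over the observed sites -- counts
    ``rep_y`` (n_reps, n_obs), latents ``rep_L``, sample sizes ``n``, site
    coordinates ``sites`` and the latent-subtracted residuals ``rep_resid``.
    """
    from scipy.interpolate import make_smoothing_spline
    n_reps = rep_y.shape[0]
    out = np.empty(n_reps)
    w = n.astype(float)
    for r in range(n_reps):
        frac = rep_y[r] / n
        spl = make_smoothing_spline(sites.astype(float), frac, w=w, lam=smoothing)
        pseudo_obs = frac - np.clip(spl(sites.astype(float)), 0.0, 1.0)
        rest = np.delete(rep_resid, r, axis=0).ravel()
        out[r] = ecdf_compare(pseudo_obs, rest)
    return out


@dataclass
class ResidualReport:
    """Per-time residual decomposition aligned to observed sites."""

    times: np.ndarray
    fitted_mask: np.ndarray                  # True where the time was fitted
    sites: list = field(default_factory=list)          # observed site indices per time
    obs_resid: list = field(default_factory=list)      # y/n - spline
    rep_resid: list = field(default_factory=list)      # (n_reps, n_obs): y_rep/n - L_rep
    proc_resid: list = field(default_factory=list)     # L_model - spline
    noise: np.ndarray | None = None                    # per-time noise scale
    ecdf_distance: np.ndarray | None = None            # observed vs pooled replicated
    ecdf_null: list = field(default_factory=list)      # per-time null distances

    def max_process_residual(self, time: float) -> float:
        j = int(np.flatnonzero(np.isclose(self.times, time))[0])
        return float(np.max(np.abs(self.proc_resid[j])))


def residual_decomposition(data: CountData, reps: ReplicatedDataset,
                           L_model: np.ndarray, splines: dict,
                           fitted_times) -> ResidualReport:
    """Decompose data-model discrepancy into measurement and process parts.

    Parameters
    ----------
    L_model : array (n_times, n_cells)
        Latent prediction of the fitted model (e.g. at the posterior mean).
    splines : {time: SplineProfile}
        Smoothed data reference per checked time.
    fitted_times : iterable of float
        Times used in the fit; the rest are flagged out-of-sample.
    """
    times = data.grid.times
    for t in times:
        if float(t) not in {float(s) for s in splines}:
            raise ValueError(f"missing spline for time {t}")
    if L_model.shape != data.n.shape:
        raise ValueError("L_model must match the data grid")
    if reps.ys.shape[1:] != data.n.shape:
        raise ValueError("replicates must match the data grid")
    fitted = np.array([float(t) in {float(s) for s in fitted_times} for t in times])
    rep = ResidualReport(times=times, fitted_mask=fitted)
    nu = np.empty(len(times))
    dist = np.empty(len(times))
    for j, t in enumerate(times):
        spl = splines[float(t)]
        m = data.n[j] > 0
        n = data.n[j][m].astype(float)
        smooth = spl.fitted[m]
        obs = data.y[j][m] / n - smooth
        rrep = reps.ys[:, j, m] / n[None, :] - reps.Ls[:, j, m]
        proc = L_model[j][m] - smooth
        rep.sites.append(np.flatnonzero(m))
        rep.obs_resid.append(obs)
        rep.rep_resid.append(rrep)
        rep.proc_resid.append(proc)
        nu[j] = noise_scale(data, spl, float(t))
        dist[j] = ecdf_compare(obs, rrep)
        rep.ecdf_null.append(ecdf_null_distances(
            reps.ys[:, j, m], reps.Ls[:, j, m], n, data.grid.sites[m], rrep,
            smoothing=spl.smoothing))
    rep.noise = nu
    rep.ecdf_distance = dist
    return rep


def characteristic_plane(data_fields: np.ndarray, model_fields: np.ndarray,
                         times, coarse_bins: tuple = (4, 6)) -> dict:
    """Block-averaged (time x position) matrices for coarse model-data comparison.

    In the characteristic plane, level sets of the labelled fraction trace
    curves of slope 1/v; block-averaging both surfaces onto a coarse grid
    (default 4 temporal x 6 spatial blocks) makes the comparison fair at the
    resolution the data support.  Empty blocks are NaN (missing, never zero).
    """
    data_fields = np.atleast_2d(np.asarray(data_fields, dtype=float))
    model_fields = np.atleast_2d(np.asarray(model_fields, dtype=float))
    if data_fields.shape != model_fields.shape:
        raise ValueError("data and model field matrices must share a shape")
    n_t, n_x = data_fields.shape
    nt_b, nx_b = coarse_bins
    t_edges = np.linspace(0, n_t, nt_b + 1).astype(int)
    x_edges = np.linspace(0, n_x, nx_b + 1).astype(int)

    def block(mat):
        out = np.full((nt_b, nx_b), np.nan)
        for a in range(nt_b):
            for b in range(nx_b):
                blk = mat[t_edges[a]:t_edges[a + 1], x_edges[b]:x_edges[b + 1]]
                blk = blk[np.isfinite(blk)]
                if blk.size:
                    out[a, b] = blk.mean()
        return out

    dmat, mmat = block(data_fields), block(model_fields)
    return {
        "data": dmat,
        "model": mmat,
        "absdiff": np.abs(dmat - mmat),
        "time_edges": np.asarray(times, dtype=float)[np.clip(t_edges, 0, n_t - 1)],
        "x_edges": x_edges,
    }


@dataclass
class MisfitExperiment:
    """Late-time misfit probe: uniform rate reduction vs higher-order terms."""

    reduction: float
    target_time: float
    profiles: dict          # variant name -> predicted profile at target_time
    reference: np.ndarray   # data spline at target_time (observed sites)
    sites: np.ndarray
    sup_distance: dict      # variant name -> sup |profile - reference|


def misfit_experiment(posterior: PosteriorSamples, reduction: float,
                      data: CountData, forward: ForwardModel,
                      target_time: float) -> MisfitExperiment:
    """Compare candidate explanations of late-time misfit at ``target_time``.

    Four predictions at the posterior-mean rates: the advection model and the
    finite-cell-size (Fokker-Planck) variant, each at the fitted rates and at
    rates uniformly scaled by (1 - reduction) -- the latter approximating
    slowly time-varying (e.g. circadian) rates.  Each profile's sup distance
    to the smoothed data at the target time is reported.
    """
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must lie in [0, 1]")
    from .measurement import fit_reference_spline
    k_mean = posterior.mean()
    spl = fit_reference_spline(data, target_time, forward.cfg.spline_smoothing)
    j = data.grid.time_index(target_time)
    m = data.n[j] > 0
    sites = np.flatnonzero(m)
    ref = spl.fitted[m]
    profiles, dists = {}, {}
    for model in ("advection", "fokker_planck"):
        for scale, tag in ((1.0, "fitted"), (1.0 - reduction, "reduced")):
            L = forward.predict(k_mean, [target_time], process_model=model,
                                scale=scale)[0]
            name = f"{model}_{tag}"
            profiles[name] = L
            dists[name] = float(np.max(np.abs(L[m] - ref)))
    return MisfitExperiment(reduction=reduction, target_time=target_time,
                            profiles=profiles, reference=ref, sites=sites,
                            sup_distance=dists)
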