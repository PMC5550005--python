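# Methods

## Model

The observable at grid point `s = (i, t)` — cell position `i` (0 at the crypt
base, spacing one cell) and collection time `t` (minutes) — is the number of
labelled strips `y_s` among `n_s` sampled.  Strips are assumed independent
(they come from different crypt–villus units or animals), and treatment `E`
is assumed to act only on the proliferation rates, giving the causal chain
`E → k → L → y` and the factorisation

    p(y, L, k | n, E) = p(y | L, n) · p(L | k) · p(k | E).

**Measurement.**  `y_s ~ Binomial(n_s, L_s)` with `L_s` the latent labelled
fraction (occupancy probability).  The likelihood is implemented without the
binomial coefficient, which is constant in `L` and `k`; the omitted constant
affects no posterior quantity.  Conventions: `0·log 0 = 0`; impossible
observations give `−∞`; sites with `n_s = 0` are excluded everywhere.  The
normal approximation `y/n ~ N(L, L(1−L)/n)` is provided for residual
interpretation only and refuses degenerate `L ∈ {0, 1}`.

**Process.**  A division at site `j` (probability `k_j Δt` per step) shifts
every cell above: `l_i ← l_{i−1}` for `i ≥ j+1`, the top cell leaving the
finite strip (open villus tip; the data's strips end, and no reflux mechanism
exists).  Averaging strips and assuming independence between a site's
occupancy and concurrent division events — adopted as the model definition —
gives the single-site master equation

    dp_i/dt = K_i (p_{i−1} − p_i),      K_i = Σ_{j<i} k_j ,

a linear lower-bidiagonal system; site 0 is invariant.  Its coarse-grained
limit is the colour (advection) equation `∂L/∂t + v ∂L/∂x = 0` with
`v(x) = ∫₀ˣ k`, and retaining the next order in the cell size gives the
Fokker–Planck correction `∂L/∂t + v ∂L/∂x = D ∂²L/∂x²`, `D = ½ Δx v(x)` —
the modified equation of the master equation, i.e. the finite-cell-size
spreading of steep fronts.

Position convention: site `i` sits at continuum coordinate `x = i`.  With
per-cell rates constant on `[j, j+1)`, `K_i = v(i)` exactly, so discrete and
continuum models align with no half-cell offset.

**Prior.**  Rates live on m = 5 equal regions over the 30-cell crypt (zero
beyond the crypt end by default — proliferation shuts off past the crypt);
`k ~ N(μ, C)`, `C = D R D`, `R_ij = exp(−(i−j)²/(2 l_c²))`.  The kernel
formula is authoritative; the loose phrase "decays to 1/e at lag l_c"
actually corresponds to lag `√2·l_c` for this kernel.  The prior is not
truncated at zero: small negative net rates (loss exceeding division) are
physically meaningful and appear in posteriors.  The log-density uses the
standard multivariate-normal normalisation.

## Parameters, units, defaults

| parameter | default | units | why |
|---|---|---|---|
| grid | 60 cells, crypt end 30 | cells | mouse small-intestine crypt+villus column at cell resolution |
| m, l_c | 5 regions, l_c = 1 | — | coarse compartment-like regions; correlation length of ~1 region |
| μ | rise to 2·10⁻³ at region 3, decay 0.5/region | min⁻¹ | mid-crypt proliferation peak, shut-off toward the crypt end |
| σ | 2·10⁻³ each region | min⁻¹ | weakly informative: spans ~0–2× the mean trend, admits negatives |
| jitter | 10⁻¹² relative | — | numerical positive-definiteness |
| true k* (generator) | (0.5, 1.1, 1.8, 1.0, 0.6)·10⁻³ | min⁻¹ | peak ≈ half-day cell cycle; end-of-crypt v = 0.03 cells/min ≈ 1.8 cells/h |
| initial bump | centre 12, width 36, height 0.8 | cells, fraction | S-phase labelling peaked mid-crypt, confined to the proliferative zone |
| n per site | 30 | strips | order of strips scored per mouse per timepoint |
| schedules | healthy 120/360/600/1080; blocked 1140/1260/1500/1620; recovering 1620/2520 | min | standard pulse-chase design; one initial, 1–2 fitted, the rest held out |
| treatment scales | healthy 1.0, blocked 0.02, recovering 0.5 | — | near-total block, partial recovery |
| circadian option | amplitude 0.2, period 1440, cosine | — | slow rate modulation for misfit studies |
| MCMC | 32 walkers × 2000 steps, burn-in 500 | — | stable split-R̂ (< 1.1) at desk scale for m = 5 |
| likelihood floor | clip L into [10⁻⁹, 1−10⁻⁹] | — | proposals whose front misses observed label are heavily penalised yet finite |

The generator's bump geometry and k* were chosen once, jointly, so the
synthetic experiments exhibit the study's qualitative regimes — smooth enough
that the continuum limit is faithful (advection within 0.05 of the master
equation at the fitted times), fast and steep enough that the circadian
variant leaves a detectable late-time process misfit while the front stays on
the 60-cell grid at 1080 min — at magnitudes realistic for mouse gut.

## Numerics

* **Master equation**: classical RK4 with internal sub-steps bounded by
  `Δt·max K ≤ 0.05`; error ~(ΔtK)⁴ per step (verified against the matrix
  exponential to 10⁻⁶).
* **Advection**: first-order upwind on a refined axis (2 nodes/cell by
  default), explicit stepping under a CFL bound with internal sub-stepping —
  never silent instability.  The scheme is monotone (maximum principle,
  total variation non-increasing).  The upwind direction follows the local
  sign of `v`, handling negative-rate pockets from the untruncated prior.
  No boundary data at `x = 0` (`v(0) = 0` removes the inflow characteristic);
  outflow at the top.
* **Fokker–Planck**: operator splitting — explicit upwind advection plus
  implicit (backward-Euler) tridiagonal diffusion — with zero diffusive flux
  at both ends; converges to the advection solution as `Δx → 0`.
* **Characteristics**: `dx/dt = v(x)` via RK45 at rtol 10⁻¹⁰.
* **Spline reference**: cubic smoothing spline on (site, y/n) weighted by n,
  roughness penalty chosen by generalised cross-validation unless given;
  evaluations clipped to [0, 1].  Needs ≥ 5 observed sites.
* **MCMC**: affine-invariant ensemble sampler.  Walkers are initialised in
  two stages: prior draws (non-finite posteriors redrawn) seed a short pilot
  (≤ 200 steps), then all walkers restart in a small ball (2% of the prior σ)
  around the best pilot point.  One-stage prior initialisation can leave a
  cold cluster of walkers stuck for thousands of steps (split-R̂ up to ~13 in
  the low-information blocked fits); the two-stage scheme restores R̂ ≈ 1.05.
  Acceptance < 1% raises a diagnostic error.

## Model-checking operationalisation

* **Measurement check.**  Observed residuals `y/n − spline` are compared with
  posterior-predictive replicated residuals `y_rep/n − L_rep` by the
  two-sample Kolmogorov–Smirnov sup distance, observed vs. all replicates
  pooled.  The two residual types are *not* identically distributed even
  under a perfect model (the spline absorbs part of the observed noise), so
  the null distribution is simulated by treating each replicate in turn as
  pseudo-data — refitting a spline to its counts and measuring its distance
  to the pool of the rest.  A distance below the null's 95th percentile at
  every fitted time counts as a pass.
* **Process check.**  Process residuals `L_model(posterior mean) − spline`
  are summarised per time by the maximum of a 5-cell moving average:
  process error is spatially smooth (transport error of a smooth field),
  whereas site-level spline noise alternates in sign, so the averaging
  suppresses noise by ~1/√5 while retaining systematic offsets.  The summary
  is compared against twice the measurement-noise scale
  `ν_t = mean_i √(L̃_i(1−L̃_i)/n_i)` (spline-based, observed sites only).
* **Misfit probe.**  At the late unfitted time, predictions at the
  posterior-mean rates are compared with predictions at uniformly reduced
  rates (default 20%, exposed as a parameter) and with the Fokker–Planck
  variant, by sup distance to the data spline — separating "slow time
  variation of rates" from "finite-cell-size physics" as explanations.
* **Characteristic plane.**  Data-spline and model surfaces are
  block-averaged (default 4 time × 6 space blocks; empty blocks are missing,
  never zero) for a coarse comparison in the plane where level sets have
  slope 1/v.

## Calibration experiments and the spline initial condition

The inference holds the smoothing spline of the first observation time fixed
as the initial condition.  When synthetic data are generated from the *bump*
itself, that spline is a slightly mis-specified IC (it over-smooths the steep
edge), which biases inferred end-of-crypt velocity by roughly +0.003
cells/min and drags 95%-interval coverage to ~0.81 — a property of the
spline approximation, not of the inference machinery.  Experiments whose
purpose is calibration therefore use a spline-realisable truth
(`workflows.well_specified_dataset`): counts at the initial time are drawn
from the bump, the spline is fitted exactly as inference will fit it, and the
later latent fields are that spline advected under the true rates.  Under
this design the 20-replicate coverage study recovers ~95% coverage and the
blocked-condition velocity estimate is unbiased.  The bump-generated variant
remains the default everywhere else, precisely because its residual IC
mismatch is the realistic situation.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: independent
strips, binomial sampling with n ≈ 30/site, a labelled bump confined to the
proliferative zone, treatment as a pure rescaling of rates, and optional slow
rate modulation.  It does not emulate: two-dimensional crypt geometry or
within-crypt strip correlation, angled-sectioning bias, label dilution across
divisions, staining chemistry, or per-animal random effects.  Passing tests
therefore demonstrate the pipeline's correctness and calibration under its
own assumptions, not robustness to those unmodelled features.

## Known limitations

* The discard-at-top boundary is a modelling choice; behaviour of real strips
  near the villus tip is not represented.
* The ensemble-mean ↔ master-equation equivalence relies on the independence
  assumption in the derivation; it is verified numerically, not proved.
* Posterior means of near-zero velocities (blocked condition) carry a
  sampling noise floor of ~0.002–0.003 cells/min set by n = 30 and a single
  fitted interval; single-seed contrasts near a sharp threshold can
  occasionally land outside it.
* The circadian option is one specific waveform (cosine, 24 h); it serves the
  diagnostic logic, not inference of time-varying rates, which is out of
  scope.
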