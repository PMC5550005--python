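# cryptdrift

Hierarchical Bayesian inference of cell proliferation and migration along the
intestinal crypt–villus axis from pulse-labelling "strip" counts.

## The problem

In pulse-chase labelling experiments (BrdU/IdU), proliferating cells in
intestinal crypts incorporate label, and the labelled cohort is then carried
up the crypt–villus axis by the mitotic pressure of cells dividing below it.
The data are one-cell-wide strips of epithelium scored 0/1 for label at each
cell position `i` (0 at the crypt base) and collection time `t`: at each grid
point, `y` labelled strips out of `n` sampled.  The scientific questions are
how fast cells proliferate and migrate under healthy conditions, after a
proliferation block (e.g. Ara-C), and during recovery — and whether a simple
proliferation-driven transport model accounts for the observations.

## The model

The analysis is a three-layer hierarchy with conditionally independent levels,
`p(y, L, k | n, E) = p(y | L, n) · p(L | k) · p(k | E)`:

* **Measurement**: counts are binomial, `y_s ~ B(n_s, L_s)`, where `L` is the
  latent labelled fraction (occupancy probability).  A normal approximation
  with `σ_s = √(L_s(1−L_s)/n_s)` is used when interpreting residuals.
* **Process** (deterministic link `L = f(k)`), at three resolutions:
  * site-level master equation `dp_i/dt = K_i (p_{i−1} − p_i)` with
    `K_i = Σ_{j<i} k_j`, derived from division events at site `j` shifting all
    cells above one position up (an exact event-driven strip simulator
    realises the same mechanism);
  * its continuum ("colour"/advection) limit `∂L/∂t + v(x) ∂L/∂x = 0` with
    `v(x) = ∫₀ˣ k(x′) dx′`;
  * a finite-cell-size Fokker–Planck correction
    `∂L/∂t + v ∂L/∂x = D(x) ∂²L/∂x²`, `D = ½ Δx v(x)`.
* **Prior**: net rates on m = 5 coarse crypt regions, `k ~ N(μ, C)` with
  `C = D R D`, squared-exponential correlation
  `R_ij = exp(−(i−j)²/(2 l_c²))`, and a mean trend rising from the crypt base
  to mid-crypt before decaying.

Posteriors over `k` are sampled with the affine-invariant ensemble sampler
(emcee); the initial labelled profile is a smoothing spline of the first
observation time, held fixed.  Model checking decomposes data–model
discrepancy into measurement residuals (`y/n −` spline, compared by ECDF
distance against posterior-predictive replicates) and process residuals
(model `−` spline), and probes late-time misfit with uniform rate reductions
vs. the Fokker–Planck variant.

## Worked example

There are no public data for this design, so the package ships a generator
that emulates the full experiment (`E → k → L → y`).  End to end from a
shell:

```bash
cryptdrift generate --seed 5 --out counts.csv --truth-out truth/
cryptdrift fit --counts counts.csv --init-time 120 --fit-times 360,600 \
               --seed 6 --out posterior.csv
```

or through the library (the numbered drivers under `analysis/` run exactly
this):

```bash
python analysis/01_simulate_experiments.py
python analysis/02_fit_healthy.py
```

which prints, for the default healthy scenario (60 cells, 5 regions, n = 30
strips/site):

```
 region  true_k  posterior_mean    ci95_lo   ci95_hi   rhat
      1  0.0005      0.00078272 0.00039568 0.0011628 1.0359
      2  0.0011      0.00057612 -0.0004156 0.0016643 1.0341
      3  0.0018       0.0013265 0.00022568 0.0023602 1.0507
      4   0.001       0.0015944 0.00039055 0.0028154 1.0385
      5  0.0006      0.00094874 4.7667e-05    0.0018 1.0456

end-of-crypt velocity: 0.0314 cells/min (1.88 cells/h)
true rates inside 95% CI: 5/5; acceptance fraction 0.55
```

The five region rates are net divisions per cell per minute; their running
integral is the migration velocity, so ~0.03 cells/min at the crypt end means
a labelled front climbing roughly two cell positions per hour, and all five
generating rates are recovered inside their 95% credible intervals.
`analysis/03` prints the treatment contrast (end-of-crypt velocity 0.0314 →
0.0045 cells/min under the block, 0.0145 during recovery); `analysis/04` shows
the measurement-residual ECDF distances below their simulated null at the
fitted times; `analysis/05` shows the circadian scenario's process residual at
the unfitted 1080 min time reaching 2.8× the measurement-noise scale, with a
uniform 20% rate reduction shrinking the sup misfit from 0.224 to 0.140 while
the Fokker–Planck variant alone only reaches 0.195.

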