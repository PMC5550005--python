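"""Prior parameter model: Gaussian random field over coarse region rates.

Net proliferation rates are modelled on m coarse regions (default m = 5) along
the crypt, coarser than the cell grid, in the spirit of compartment models.
The prior over the region rate vector k is multivariate normal N(mu, C) with

    C = D R D,    D = diag(sigma),    R_ij = exp(-(i - j)^2 / (2 lc^2)),

i.e. elementwise C_ij = sigma_i sigma_j R_ij.  The squared-exponential
correlation length ``lc`` (in region-index units) controls the smoothness of
realisations; with this kernel the correlation falls to 1/e at lag sqrt(2) lc
(the kernel formula is authoritative; "decays to 1/e at lag lc" is loose
shorthand).  The prior is deliberately NOT truncated at zero: small negative
net rates (loss exceeding division) are admissible and do occur in posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .continuum import RateFunction

__all__ = [
    "PriorSpec",
    "RegionMap",
    "build_correlation",
    "build_covariance",
    "sample_prior",
    "prior_logpdf",
    "expand_to_grid",
    "default_mean_trend",
]


def default_mean_trend(m: int, peak_region: int, decay: float, peak_value: float = 0.002) -> np.ndarray:
    """Mean-trend preset: rates rising to a mid-crypt peak then decaying geometrically.

    ``peak_region`` is 1-based; the trend is ``peak_value * decay**|r - peak_region|``
    so the profile rises from the crypt base to the peak and falls by a factor
    ``decay`` per region beyond it (``decay = 0`` zeroes everything off-peak).
    """
    if not 1 <= peak_region <= m:
        raise ValueError("peak_region must lie in 1..m")
    lag = np.abs(np.arange(1, m + 1) - peak_region).astype(float)
    with np.errstate(invalid="ignore"):
        mu = peak_value * np.where(lag == 0, 1.0, float(decay) ** lag)
    return mu


@dataclass
class PriorSpec:
    """Hyperparameters of the N(mu, DRD) prior over the m region rates [1/min]."""

    m: int = 5
    mu: np.ndarray = field(default_factory=lambda: default_mean_trend(5, 3, 0.5, 0.002))
    sigma: np.ndarray = field(default_factory=lambda: np.full(5, 2e-3))
    lc: float = 1.0
    jitter: float = 1e-12  # relative to the largest diagonal entry

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (self.m,) or self.sigma.shape != (self.m,):
            raise ValueError(f"mu and sigma must have shape ({self.m},)")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if self.lc <= 0:
            raise ValueError("correlation length lc must be positive")


def build_correlation(m: int, lc: float) -> np.ndarray:
    """Squared-exponential correlation matrix R_ij = exp(-(i-j)^2 / (2 lc^2))."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if lc <= 0:
        raise ValueError("lc must be positive")
    idx = np.arange(m)
    lag = idx[:, None] - idx[None, :]
    return np.exp(-(lag.astype(float) ** 2) / (2.0 * lc**2))


def build_covariance(spec: PriorSpec) -> np.ndarray:
    """C = D R D + jitter*I with D = diag(sigma); validated positive definite."""
    R = build_correlation(spec.m, spec.lc)
    C = np.outer(spec.sigma, spec.sigma) * R
    eps = spec.jitter * max(float(np.max(np.diag(C))), 1.0e-300)
    C = C + eps * np.eye(spec.m)
    try:
        linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - jitter normally suffices
        raise linalg.LinAlgError(
            f"prior covariance not positive definite even after jitter {eps:g}: {exc}"
        )
    return C


def sample_prior(spec: PriorSpec, n_draws: int, seed) -> np.ndarray:
    """I.i.d. draws k ~ N(mu, C), shape (n_draws, m); reproducible under seed."""
    rng = np.random.default_rng(seed)
    C = build_covariance(spec)
    Lch = linalg.cholesky(C, lower=True)
    z = rng.standard_normal((n_draws, spec.m))
    return spec.mu[None, :] + z @ Lch.T


def prior_logpdf(k: np.ndarray, spec: PriorSpec) -> float:
    """Log density of N(mu, C) at k (standard normalisation)."""
    C = build_covariance(spec)
    Lch = linalg.cholesky(C, lower=True)
    r = np.asarray(k, dtype=float) - spec.mu
    w = linalg.solve_triangular(Lch, r, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(Lch)))
    return float(-0.5 * (spec.m * np.log(2.0 * np.pi) + logdet + w @ w))


@dataclass(frozen=True)
class RegionMap:
    """Partition of [0, crypt end] into m coarse regions, in cell units.

    ``bounds`` has m+1 strictly increasing entries starting at 0.  With
    ``zero_beyond_end`` set (default), the rate is 0 on (last bound, n_cells]:
    proliferation shuts off past the crypt end.
    """

    bounds: np.ndarray
    zero_beyond_end: bool = True

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 1 or len(b) < 2:
            raise ValueError("bounds must have at least two entries")
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("bounds must start at 0 and increase strictly")
        object.__setattr__(self, "bounds", b)

    @property
    def m(self) -> int:
        return len(self.bounds) - 1

    @classmethod
    def equal_regions(cls, m: int = 5, crypt_end: float = 30.0, zero_beyond_end: bool = True) -> "RegionMap":
        return cls(bounds=np.linspace(0.0, crypt_end, m + 1), zero_beyond_end=zero_beyond_end)


def expand_to_grid(k_regions: np.ndarray, region_map: RegionMap, n_cells: int):
    """Expand the coarse rate vector to the cell grid.

    Returns ``(k_fine, rate_fn)``: per-cell rates (cell j = value of the region
    containing [j, j+1)) and the matching piecewise-constant
    :class:`RateFunction` on [0, n_cells].
    """
    k_regions = np.asarray(k_regions, dtype=float)
    if k_regions.shape != (region_map.m,):
        raise ValueError(f"expected {region_map.m} region rates, got shape {k_regions.shape}")
    if region_map.bounds[-1] > n_cells:
        raise ValueError("region bounds extend beyond the grid")
    breaks, values = region_map.bounds, k_regions
    if region_map.bounds[-1] < n_cells:
        # pad to the top of the grid: zero rate past the crypt end, or carry the
        # last region's rate when zero enforcement is disabled
        pad = 0.0 if region_map.zero_beyond_end else float(k_regions[-1])
        breaks = np.concatenate([breaks, [float(n_cells)]])
        values = np.concatenate([values, [pad]])
    fn = RateFunction(breaks=breaks, values=values)
    k_fine = fn.cell_averages(n_cells)
    return k_fine, fn
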