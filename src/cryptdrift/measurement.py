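"""Measurement layer: space-time grid, binomial strip-count model, spline reference.

The experiment scores one-cell-wide "strips" of epithelium 0/1 for label at each
position ``i`` along the crypt-villus axis (``i = 0`` at the crypt base) and each
collection time ``t`` (minutes).  The observable at a grid point is the number of
labelled strips ``y`` out of ``n`` sampled, modelled as independent binomial draws
with success probability equal to the latent labelled fraction (occupancy
probability) ``L``.

Position convention: site ``i`` sits at continuum coordinate ``x = i`` (cell
widths).  With per-cell rates constant on ``[j, j+1)`` this makes the discrete and
continuum process models align exactly (see :mod:`cryptdrift.discrete`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.special import xlog1py, xlogy

__all__ = [
    "SpaceTimeGrid",
    "CountData",
    "LabelFractionField",
    "SplineProfile",
    "binomial_loglik",
    "gaussian_approx_loglik",
    "sample_measurements",
    "fit_reference_spline",
]


@dataclass(frozen=True)
class SpaceTimeGrid:
    """Discrete observation grid: ``n_cells`` sites x ordered times (minutes)."""

    n_cells: int
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if self.n_cells < 2:
            raise ValueError(f"n_cells must be >= 2, got {self.n_cells}")
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-d array")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def sites(self) -> np.ndarray:
        """Continuum coordinates of the sites (x = i, cell units)."""
        return np.arange(self.n_cells, dtype=float)

    def time_index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size != 1:
            raise KeyError(f"time {t} min not on grid {self.times}")
        return int(idx[0])


@dataclass
class CountData:
    """Labelled strip counts ``y`` out of ``n`` sampled on a space-time grid.

    ``n`` and ``y`` are integer arrays of shape ``(n_times, n_cells)``; grid points
    that were never sampled carry ``n = 0`` and are excluded from likelihoods.
    """

    grid: SpaceTimeGrid
    n: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.grid.n_times, self.grid.n_cells)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.n.shape != shape or self.y.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got n {self.n.shape}, y {self.y.shape}"
            )
        if np.any(self.n < 0):
            raise ValueError("sample sizes n must be nonnegative")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("labelled counts must satisfy 0 <= y <= n")

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of grid points with at least one sampled strip."""
        return self.n > 0

    def fractions(self) -> np.ndarray:
        """Observed labelled fractions y/n; NaN where n = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.y / np.maximum(self.n, 1), np.nan)

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(n, y) row vectors for one observation time."""
        j = self.grid.time_index(t)
        return self.n[j], self.y[j]


@dataclass
class LabelFractionField:
    """Latent labelled fraction L(x, t) tabulated on a fine axis x at given times."""

    x: np.ndarray
    times: np.ndarray
    values: np.ndarray  # shape (n_times, len(x))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.times), len(self.x)):
            raise ValueError("values must have shape (n_times, len(x))")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("labelled fractions must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def at_time(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size != 1:
            raise KeyError(f"time {t} not tabulated")
        return self.values[int(idx[0])]

    def on_sites(self, grid: SpaceTimeGrid) -> np.ndarray:
        """Interpolate onto a grid's sites for every tabulated time.

        Times must match the grid's times exactly.
        """
        if len(self.times) != grid.n_times or not np.allclose(self.times, grid.times):
            raise ValueError("field times do not match grid times")
        out = np.empty((grid.n_times, grid.n_cells))
        for j in range(grid.n_times):
            out[j] = np.interp(grid.sites, self.x, self.values[j])
        return out


def _aligned_L(data: CountData, L) -> np.ndarray:
    """Coerce L (array or LabelFractionField) to an array on data's grid."""
    if isinstance(L, LabelFractionField):
        arr = L.on_sites(data.grid)
    else:
        arr = np.asarray(L, dtype=float)
        if arr.shape == (data.grid.n_cells,) and data.grid.n_times == 1:
            arr = arr[None, :]
    if arr.shape != data.n.shape:
        raise ValueError(f"L has shape {arr.shape}, expected {data.n.shape}")
    return arr


def binomial_loglik(data: CountData, L) -> float:
    """Coefficient-free binomial log-likelihood sum_s [y log L + (n-y) log(1-L)].

    The binomial coefficient is omitted (it is constant in the latent field and
    the rate parameters, so posterior inference is unaffected).  Conventions:
    0*log 0 = 0; returns ``-inf`` when an impossible observation occurs (y > 0
    with L = 0, or y < n with L = 1).  Sites with n = 0 are excluded.
    """
    Larr = _aligned_L(data, L)
    if np.any((Larr < 0) | (Larr > 1)):
        raise ValueError("L values must lie in [0, 1]")
    m = data.observed
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(data.y[m], Larr[m]) + xlog1py(data.n[m] - data.y[m], -Larr[m])
    return float(np.sum(terms))


def gaussian_approx_loglik(data: CountData, L) -> float:
    """Normal approximation to the binomial likelihood of the observed fractions.

    Per observed site: ``-log(sigma sqrt(2 pi)) - (y/n - L)^2 / (2 sigma^2)`` with
    ``sigma = sqrt(L (1 - L) / n)``.  Degenerate at L in {0, 1}: raises, because
    the variance vanishes; callers must mask such sites or use the exact
    binomial likelihood.
    """
    Larr = _aligned_L(data, L)
    m = data.observed
    Lm = Larr[m]
    if np.any((Lm <= 0) | (Lm >= 1)):
        raise ValueError(
            "normal approximation undefined at L in {0, 1}; mask those sites "
            "or use binomial_loglik"
        )
    n = data.n[m].astype(float)
    var = Lm * (1.0 - Lm) / n
    resid = data.y[m] / n - Lm
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * var) - resid**2 / (2.0 * var)))


def sample_measurements(L, n, seed) -> CountData:
    """Draw strip counts y ~ Binomial(n, L) independently at every grid point.

    Parameters
    ----------
    L : LabelFractionField or array (n_times, n_cells)
        Latent labelled fractions; if a field, must carry grid-compatible times.
    n : int or array
        Strips sampled per grid point (broadcast against L's shape).
    seed : int or numpy Generator
    """
    rng = np.random.default_rng(seed)
    if isinstance(L, LabelFractionField):
        grid = SpaceTimeGrid(n_cells=len(L.x), times=L.times)
        if not np.allclose(L.x, np.arange(len(L.x))):
            raise ValueError("sample_measurements needs L tabulated on integer sites")
        Larr = L.values
    else:
        # bare array: synthesise a grid with placeholder times 0..T-1
        Larr = np.atleast_2d(np.asarray(L, dtype=float))
        grid = SpaceTimeGrid(n_cells=Larr.shape[1], times=np.arange(Larr.shape[0], dtype=float))
    narr = np.broadcast_to(np.asarray(n, dtype=np.int64), Larr.shape).copy()
    y = rng.binomial(narr, np.clip(Larr, 0.0, 1.0))
    return CountData(grid=grid, n=narr, y=y)


@dataclass
class SplineProfile:
    """Cubic smoothing spline through observed fractions at one time, clipped to [0,1]."""

    knots: np.ndarray
    fitted: np.ndarray          # values at the full set of sites, clipped
    smoothing: float | None     # lambda passed to the fitter (None = GCV choice)
    _spline: object = field(repr=False, default=None)

    def __call__(self, x) -> np.ndarray:
        return np.clip(self._spline(np.asarray(x, dtype=float)), 0.0, 1.0)


def fit_reference_spline(data: CountData, time: float, smoothing: float | None = None) -> SplineProfile:
    """Fit the smoothed reference profile of observed fractions at one time.

    Used both as the (fixed) initial condition for the process models and as the
    smooth data reference when decomposing residuals.  A cubic smoothing spline
    is fitted to (site, y/n) over sites with n > 0, weighted by n; ``smoothing``
    is the scalar roughness penalty (``None`` selects it by generalised
    cross-validation).  Evaluations are clipped to [0, 1].
    """
    j = data.grid.time_index(time)
    mask = data.n[j] > 0
    xs = data.grid.sites[mask]
    if xs.size < 5:
        raise ValueError(f"need at least 5 observed sites to fit a spline, got {xs.size}")
    frac = data.y[j][mask] / data.n[j][mask]
    w = data.n[j][mask].astype(float)
    spl = make_smoothing_spline(xs, frac, w=w, lam=smoothing)
    fitted = np.clip(spl(data.grid.sites), 0.0, 1.0)
    return SplineProfile(knots=xs, fitted=fitted, smoothing=smoothing, _spline=spl)
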