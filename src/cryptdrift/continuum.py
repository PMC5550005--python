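"""Continuum process models: colour (advection) equation and Fokker-Planck correction.

The coarse-grained labelled fraction L(x, t) obeys the non-conservative colour
equation

    dL/dt + v(x) dL/dx = 0,      v(x) = int_0^x k(x') dx',

whose solutions are constant along characteristics dx/dt = v(x).  Retaining the
next order in the cell size Delta-x yields an advection-diffusion (Fokker-Planck)
correction

    dL/dt + v dL/dx = D(x) d2L/dx2,      D(x) = (1/2) Delta-x v(x),

which captures finite-cell-size spreading of steep fronts (it is the modified
equation of the site-level master equation).  L is an occupancy probability, not
a density: the colour form does not conserve mass and no conservation is imposed.

Boundary handling: v(0) = 0 removes the inflow characteristic at the crypt base,
so no boundary data are needed there; the top of the domain is outflow (cells
shed from the villus tip).  For the diffusive model, zero diffusive flux is
applied at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .discrete import solve_master_equation

__all__ = [
    "RateFunction",
    "VelocityField",
    "DiffusionField",
    "PDESolution",
    "velocity_from_rates",
    "solve_advection",
    "solve_fokker_planck",
    "characteristic_curves",
    "discrete_continuum_gap",
]


@dataclass(frozen=True)
class RateFunction:
    """Piecewise-constant net proliferation rate k(x) [1/min] on [0, domain end].

    ``breaks`` are the m+1 piece edges (ascending, starting at 0); ``values``
    holds the rate on each of the m pieces.  Outside the last break the rate
    is zero.
    """

    breaks: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if b.ndim != 1 or v.ndim != 1 or len(b) != len(v) + 1:
            raise ValueError("need len(breaks) == len(values) + 1")
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("breaks must start at 0 and increase strictly")
        if not np.all(np.isfinite(v)):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "breaks", b)
        object.__setattr__(self, "values", v)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.breaks, x, side="right") - 1
        inside = (idx >= 0) & (idx < len(self.values))
        out = np.zeros_like(x, dtype=float)
        out[inside] = self.values[idx[inside]]
        return out

    def cell_averages(self, n_cells: int) -> np.ndarray:
        """Average of k over each unit cell [j, j+1), j = 0..n_cells-1."""
        edges = np.arange(n_cells + 1, dtype=float)
        V = velocity_from_rates(self)
        return np.diff(V(edges))


@dataclass(frozen=True)
class VelocityField:
    """Migration velocity v(x) = int_0^x k [cells/min]; piecewise-linear, v(0)=0."""

    knots: np.ndarray
    v_knots: np.ndarray

    def __post_init__(self) -> None:
        kn = np.asarray(self.knots, dtype=float)
        vv = np.asarray(self.v_knots, dtype=float)
        if kn.shape != vv.shape or kn.ndim != 1:
            raise ValueError("knots and v_knots must be matching 1-d arrays")
        object.__setattr__(self, "knots", kn)
        object.__setattr__(self, "v_knots", vv)

    def __call__(self, x) -> np.ndarray:
        # constant extrapolation beyond the knots (k = 0 outside the domain)
        return np.interp(np.asarray(x, dtype=float), self.knots, self.v_knots)

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.v_knots)))


@dataclass(frozen=True)
class DiffusionField:
    """Finite-cell-size diffusivity D(x) = (1/2) delta_x v(x) [cells^2/min]."""

    velocity: VelocityField
    delta_x: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")

    def __call__(self, x) -> np.ndarray:
        return 0.5 * self.delta_x * self.velocity(x)


@dataclass
class PDESolution:
    """Labelled-fraction field on the fine axis plus solver metadata."""

    x: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_times, len(x))
    scheme: str
    cfl: float
    n_nodes: int

    def at_time(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size != 1:
            raise KeyError(f"time {t} not in solution")
        return self.values[int(idx[0])]

    def on_sites(self, n_cells: int) -> np.ndarray:
        """Values at the integer site coordinates x = 0..n_cells-1."""
        sites = np.arange(n_cells, dtype=float)
        return np.vstack([np.interp(sites, self.x, row) for row in self.values])


def velocity_from_rates(k: RateFunction) -> VelocityField:
    """Exact piecewise-linear antiderivative v(x) = int_0^x k, v(0) = 0."""
    widths = np.diff(k.breaks)
    v_knots = np.concatenate(([0.0], np.cumsum(widths * k.values)))
    return VelocityField(knots=k.breaks, v_knots=v_knots)


def _prepare_ic(L0, x: np.ndarray) -> np.ndarray:
    if callable(L0):
        vals = np.asarray(L0(x), dtype=float)
    else:
        arr = np.asarray(L0, dtype=float)
        if arr.shape == x.shape:
            vals = arr.copy()
        else:
            # tabulated on integer sites; interpolate to the fine axis
            vals = np.interp(x, np.arange(arr.size, dtype=float), arr)
    return np.clip(vals, 0.0, 1.0)


def _upwind_increment(L: np.ndarray, v: np.ndarray, dx: float) -> np.ndarray:
    """First-order upwind approximation of -v dL/dx with outflow boundaries."""
    dLdt = np.empty_like(L)
    back = np.empty_like(L)
    back[1:] = L[1:] - L[:-1]
    back[0] = 0.0  # v(0) = 0: no inflow characteristic at the crypt base
    fwd = np.empty_like(L)
    fwd[:-1] = L[1:] - L[:-1]
    fwd[-1] = 0.0  # outflow at the villus tip
    vp = np.maximum(v, 0.0)
    vm = np.minimum(v, 0.0)
    dLdt[:] = -(vp * back + vm * fwd) / dx
    return dLdt


def _time_grid(times, t0: float) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < t0):
        raise ValueError("output times must be >= start time")
    return times


def solve_advection(L0, v: VelocityField, times, t0: float = 0.0, *,
                    domain_end: float | None = None, refine: int = 2,
                    cfl: float = 0.9) -> PDESolution:
    """First-order upwind finite-volume solution of the colour equation.

    ``L0`` may be a callable (e.g. a :class:`SplineProfile`), an array on the
    fine axis, or an array tabulated on integer sites.  The fine axis has
    ``refine`` nodes per cell; time stepping is explicit with sub-steps chosen
    to satisfy the CFL bound (never silently unstable).  The scheme is
    monotone: min L0 <= L <= max L0 (maximum principle) and total variation
    does not increase.  The upwind direction follows the local sign of v, so
    mildly negative net rates (posterior realisations) are handled.
    """
    if refine < 1:
        raise ValueError("refine must be >= 1")
    if domain_end is None:
        domain_end = float(v.knots[-1])
    dx = 1.0 / refine
    x = np.arange(0.0, domain_end + 0.5 * dx, dx)
    L = _prepare_ic(L0, x)
    vx = v(x)
    vmax = float(np.max(np.abs(vx)))
    dt_max = cfl * dx / vmax if vmax > 0 else np.inf
    times = _time_grid(times, t0)
    order = np.argsort(times)
    out = np.empty((len(times), x.size))
    t = t0
    for idx in order:
        span = times[idx] - t
        n_sub = max(1, int(np.ceil(span / dt_max))) if span > 0 else 0
        h = span / n_sub if n_sub else 0.0
        for _ in range(n_sub):
            L = L + h * _upwind_increment(L, vx, dx)
        t = times[idx]
        out[idx] = L
    return PDESolution(x=x, times=times, values=np.clip(out, 0.0, 1.0),
                       scheme="upwind1", cfl=cfl, n_nodes=x.size)


def solve_fokker_planck(L0, v: VelocityField, delta_x: float, times, t0: float = 0.0, *,
                        domain_end: float | None = None, refine: int = 2,
                        cfl: float = 0.9) -> PDESolution:
    """Advection-diffusion solution with D(x) = (1/2) delta_x v(x).

    Operator-split: explicit upwind advection plus implicit (backward-Euler)
    diffusion each sub-step, with zero-diffusive-flux boundaries.  As
    ``delta_x -> 0`` the solution converges to the pure advection solution.
    """
    if delta_x <= 0:
        raise ValueError("delta_x must be positive")
    if domain_end is None:
        domain_end = float(v.knots[-1])
    dx = 1.0 / refine
    x = np.arange(0.0, domain_end + 0.5 * dx, dx)
    L = _prepare_ic(L0, x)
    vx = v(x)
    Dx = np.maximum(0.5 * delta_x * vx, 0.0)  # negative-v pockets get no (unphysical) negative D
    vmax = float(np.max(np.abs(vx)))
    dt_max = cfl * dx / vmax if vmax > 0 else np.inf
    times = _time_grid(times, t0)
    order = np.argsort(times)
    M = x.size
    out = np.empty((len(times), M))

    def diffusion_matrix(h: float) -> np.ndarray:
        # banded (I - h A) with A L = D (L_{i+1} - 2 L_i + L_{i-1}) / dx^2,
        # zero-flux: ghost values mirror the boundary nodes
        r = h * Dx / dx**2
        ab = np.zeros((3, M))
        ab[0, 1:] = -r[:-1]          # superdiagonal
        ab[1, :] = 1.0 + 2.0 * r
        ab[2, :-1] = -r[1:]          # subdiagonal
        ab[1, 0] = 1.0 + r[0]
        ab[1, -1] = 1.0 + r[-1]
        return ab

    t = t0
    for idx in order:
        span = times[idx] - t
        n_sub = max(1, int(np.ceil(span / dt_max))) if span > 0 else 0
        h = span / n_sub if n_sub else 0.0
        if n_sub:
            ab = diffusion_matrix(h)
        for _ in range(n_sub):
            L = L + h * _upwind_increment(L, vx, dx)
            L = solve_banded((1, 1), ab, L)
        t = times[idx]
        out[idx] = L
    return PDESolution(x=x, times=times, values=np.clip(out, 0.0, 1.0),
                       scheme="upwind1+implicit-diffusion", cfl=cfl, n_nodes=M)


def characteristic_curves(v: VelocityField, x0_list, times, t0: float = 0.0) -> np.ndarray:
    """Trajectories x(t) of dx/dt = v(x) from each starting position.

    Along each curve the colour-equation solution is constant; in the
    characteristic plane the curves have slope 1/v.  Returns an array of shape
    (len(x0_list), len(times)).  Trajectories are clipped at the domain top.
    """
    x0_list = np.atleast_1d(np.asarray(x0_list, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    top = float(v.knots[-1])

    def rhs(t, xs):
        return v(np.clip(xs, 0.0, top))

    t_end = float(np.max(times))
    sol = solve_ivp(rhs, (t0, max(t_end, t0 + 1e-12)), x0_list, t_eval=np.sort(times),
                    rtol=1e-10, atol=1e-12, method="RK45", dense_output=False)
    if not sol.success:
        raise RuntimeError(f"characteristic integration failed: {sol.message}")
    traj = np.empty((x0_list.size, times.size))
    order = np.argsort(times)
    traj[:, order] = sol.y
    return np.clip(traj, 0.0, top)


def discrete_continuum_gap(k: RateFunction, L0, times, t0: float = 0.0, *,
                           n_cells: int | None = None, refine: int = 2,
                           delta_x: float = 1.0) -> dict:
    """Sup-norm distances between master-equation, advection and FP solutions.

    All three models share the initial condition (evaluated at the sites for
    the master equation, on the fine axis for the continuum solvers) and are
    compared on the integer site coordinates.  Returns per-time sup norms
    ``{"adv_vs_master": ..., "fp_vs_master": ..., "adv_vs_fp": ...}`` plus the
    site matrices themselves.
    """
    if n_cells is None:
        n_cells = int(round(k.breaks[-1]))
    v = velocity_from_rates(k)
    k_fine = k.cell_averages(n_cells)
    sites = np.arange(n_cells, dtype=float)
    p0 = _prepare_ic(L0, sites)
    master = solve_master_equation(p0, k_fine, times, t0=t0)
    adv = solve_advection(L0, v, times, t0=t0, domain_end=float(n_cells - 1),
                          refine=refine).on_sites(n_cells)
    fp = solve_fokker_planck(L0, v, delta_x, times, t0=t0,
                             domain_end=float(n_cells - 1), refine=refine).on_sites(n_cells)
    return {
        "times": np.atleast_1d(np.asarray(times, dtype=float)),
        "master": master,
        "advection": adv,
        "fokker_planck": fp,
        "adv_vs_master": np.max(np.abs(adv - master), axis=1),
        "fp_vs_master": np.max(np.abs(fp - master), axis=1),
        "adv_vs_fp": np.max(np.abs(adv - fp), axis=1),
    }
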