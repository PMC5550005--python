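"""Spatially discrete process model: single-site master equation and strip simulator.

A strip is a column of sites i = 0..n_cells-1 with binary label occupancy l_i.
A division at site j (rate k_j per minute) pushes every cell above j up by one
position: l_i <- l_{i-1} for all i >= j+1, the top cell falling off the villus
tip.  Averaging over strips, the occupancy probability p_i(t) = p(l_i(t) = 1)
obeys the linear master equation

    dp_i/dt = K_i (p_{i-1} - p_i),      K_i = sum_{j<i} k_j,

whose derivation requires (and we adopt as model definition) independence of
l_{i-1}(t) from the division events in the same interval.  Site 0 has an empty
sum, so p_0 is constant in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StripState",
    "OccupancyProbability",
    "cumulative_rates",
    "solve_master_equation",
    "simulate_strip_ensemble",
]


@dataclass
class StripState:
    """Binary occupancy vector of one strip at a given time (minutes)."""

    l: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l)
        if not np.isin(self.l, (0, 1)).all():
            raise ValueError("strip occupancy entries must be 0 or 1")
        self.l = self.l.astype(np.int8)


@dataclass
class OccupancyProbability:
    """Site occupancy probabilities p_i at one time stamp."""

    p: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("occupancy probabilities must lie in [0, 1]")


def cumulative_rates(k_fine: np.ndarray) -> np.ndarray:
    """Exclusive prefix sum K_i = sum_{j<i} k_j (K_0 = 0)."""
    k = np.asarray(k_fine, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("rates must be finite")
    K = np.empty_like(k)
    K[0] = 0.0
    np.cumsum(k[:-1], out=K[1:])
    return K


def solve_master_equation(p0, k_fine, times, t0: float = 0.0, max_step_fraction: float = 0.05):
    """Integrate the master equation from ``p0`` at ``t0`` to each requested time.

    The system dp_i/dt = K_i (p_{i-1} - p_i) is linear with a lower-bidiagonal
    generator; it is integrated with classical RK4 using internal sub-steps
    bounded by ``dt * max_i K_i <= max_step_fraction`` (well inside the explicit
    stability region, and accurate to ~(dt K)^4 per step).

    Returns an array of shape (len(times), n_cells).  For k >= 0 the solution
    stays in [0, 1]; net-negative rates are permitted at this probability level
    (the spec of the model, not of the event simulator) but the bound then only
    holds approximately.
    """
    p = np.asarray(p0.p if isinstance(p0, OccupancyProbability) else p0, dtype=float).copy()
    K = cumulative_rates(k_fine)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < t0):
        raise ValueError("output times must be >= start time")
    order = np.argsort(times)
    Kmax = float(np.max(np.abs(K)))
    dt_max = max_step_fraction / Kmax if Kmax > 0 else np.inf

    def rhs(q: np.ndarray) -> np.ndarray:
        dq = np.empty_like(q)
        dq[0] = 0.0
        dq[1:] = K[1:] * (q[:-1] - q[1:])
        return dq

    out = np.empty((len(times), p.size))
    t = t0
    for idx in order:
        target = times[idx]
        span = target - t
        if span > 0 and np.isfinite(dt_max):
            n_sub = max(1, int(np.ceil(span / dt_max)))
        else:
            n_sub = 1 if span > 0 else 0
        h = span / n_sub if n_sub else 0.0
        for _ in range(n_sub):
            k1 = rhs(p)
            k2 = rhs(p + 0.5 * h * k1)
            k3 = rhs(p + 0.5 * h * k2)
            k4 = rhs(p + h * k3)
            p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = target
        out[idx] = p
    if np.all(np.asarray(k_fine) >= 0):
        out = np.clip(out, 0.0, 1.0)  # shave float round-off at the bounds
    return out


def simulate_strip_ensemble(p0, k_fine, times, n_strips: int, seed):
    """Exact event-driven simulation of an ensemble of independent strips.

    Each strip starts from independent site-wise Bernoulli(p0_i) draws.  Division
    events are generated by competing exponential clocks: the total rate is
    R = sum_j k_j (constant -- divisions occur at sites, labelled or not), the
    waiting time is Exp(R) and the dividing site j is chosen with probability
    k_j / R.  The event shifts l_{j+1:} <- l_{j:-1} (top cell discarded,
    l_{j+1} duplicating the divider's label).

    Returns ``(counts, mean_occupancy)``: labelled-strip counts per site at each
    requested time, shape (len(times), n_cells), and counts / n_strips.

    Rates must be nonnegative: the simulator realises true event rates, whereas
    net-negative rates are only meaningful in the probability-level models.
    """
    k = np.asarray(k_fine, dtype=float)
    if np.any(k < 0):
        raise ValueError("simulate_strip_ensemble requires nonnegative rates")
    if n_strips < 1:
        raise ValueError("n_strips must be >= 1")
    p = np.asarray(p0.p if isinstance(p0, OccupancyProbability) else p0, dtype=float)
    t0 = p0.time if isinstance(p0, OccupancyProbability) else 0.0
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < t0):
        raise ValueError("output times must be >= start time")
    order = np.argsort(times)
    rng = np.random.default_rng(seed)
    n_cells = p.size
    R = float(k.sum())
    cum = np.cumsum(k) / R if R > 0 else None  # searchsorted sampler for the dividing site

    counts = np.zeros((len(times), n_cells), dtype=np.int64)
    for _ in range(n_strips):
        l = (rng.random(n_cells) < p).astype(np.int8)
        t = t0
        for idx in order:
            target = times[idx]
            if R > 0:
                while True:
                    wait = rng.exponential(1.0 / R)
                    if t + wait > target:
                        break
                    t += wait
                    j = int(np.searchsorted(cum, rng.random()))
                    if j + 1 < n_cells:
                        l[j + 1 :] = l[j:-1]
            t = target
            counts[idx] += l
    return counts, counts / float(n_strips)
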