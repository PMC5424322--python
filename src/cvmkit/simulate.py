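"""Exact simulation of CVM tracks and sampling-scheme generators.

Tracks are drawn from the exact joint (position, velocity)
linear-Gaussian transition between consecutive sample times — never by
Euler stepping — so simulated data are free of discretization bias at
any sampling interval and the simulator shares its kernel with the
likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import CVMParams, transition

__all__ = [
    "Track",
    "simulate",
    "simulate_multiphase",
    "subsample_random",
    "irregular_times",
    "whale_like_times",
]


@dataclass
class Track:
    """A time-stamped planar track.

    ``t`` is strictly increasing; ``x``/``y`` are positions.  Simulated
    tracks also carry the (unobservable in real data) velocity path in
    ``vx``/``vy`` for diagnostics, and multiphase simulations record
    their ``true_change_times``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    true_change_times: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal lengths")
        if len(self.t) < 2:
            raise ValueError("a track needs at least 2 positions")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.t)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _resolve_times(times=None, n: int | None = None, dt: float | None = None, t0: float = 0.0) -> np.ndarray:
    if times is not None:
        t = np.asarray(times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing vector of length >= 2")
        return t
    if n is None or dt is None:
        raise ValueError("provide either explicit times or both n and dt")
    if n < 2 or dt <= 0:
        raise ValueError("need n >= 2 and dt > 0")
    return t0 + dt * np.arange(n)


def _draw_initial_velocity(params: CVMParams, v0, rng: np.random.Generator) -> np.ndarray:
    if isinstance(v0, str):
        if v0 != "stationary":
            raise ValueError(f"unknown v0 flag {v0!r}")
        sd = params.eta / math.sqrt(2.0)
        return np.array(params.mu) + sd * rng.standard_normal(2)
    v0 = np.asarray(v0, dtype=float)
    if v0.shape != (2,):
        raise ValueError("v0 must be a 2-vector or 'stationary'")
    return v0


def _step_samplers(params: CVMParams, dts: np.ndarray):
    """Cache (transition, drift, Cholesky) per unique interval."""
    cache = {}
    for d in np.unique(dts):
        st = transition(params, float(d))
        q = st.noise_cov
        # noise_cov is PSD by construction; tiny negative eigs from
        # rounding are clipped via a safe Cholesky
        try:
            L = np.linalg.cholesky(q + 1e-300 * np.eye(4))
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(q)
            L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        cache[float(d)] = (st.transition, st.drift, L)
    return cache


def _simulate_states(
    params: CVMParams, t: np.ndarray, state0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    dts = np.diff(t)
    cache = _step_samplers(params, dts)
    out = np.empty((len(t), 4))
    out[0] = state0
    noise = rng.standard_normal((len(dts), 4))
    s = state0.copy()
    for i, d in enumerate(dts):
        T, drift, L = cache[float(d)]
        s = T @ s + drift + L @ noise[i]
        out[i + 1] = s
    return out


def simulate(
    params: CVMParams,
    times=None,
    *,
    n: int | None = None,
    dt: float | None = None,
    v0="stationary",
    z0=(0.0, 0.0),
    seed: int | np.random.Generator | None = None,
) -> Track:
    """Simulate a CVM track on an arbitrary time grid.

    Parameters
    ----------
    params:
        Model parameters.
    times:
        Explicit strictly increasing sample times; alternatively give
        ``n`` and ``dt`` for a regular grid starting at 0.
    v0:
        Initial velocity: a 2-vector, or ``"stationary"`` (default) to
        draw it from the stationary law N(mu, (eta^2/2) I).
    z0:
        Initial position.
    seed:
        Integer seed or a ``numpy.random.Generator``; a fixed seed makes
        the output bit-exactly reproducible.
    """
    t = _resolve_times(times, n, dt)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = _draw_initial_velocity(params, v0, rng)
    state0 = np.array([z0[0], v[0], z0[1], v[1]])
    states = _simulate_states(params, t, state0, rng)
    return Track(t=t, x=states[:, 0], y=states[:, 2], vx=states[:, 1], vy=states[:, 3])


def simulate_multiphase(
    phases: list[tuple[CVMParams, float]],
    dt: float,
    *,
    v0="stationary",
    z0=(0.0, 0.0),
    seed: int | np.random.Generator | None = None,
) -> Track:
    """Concatenated multi-phase simulation on a regular grid.

    Each phase is a ``(params, duration)`` pair; position and velocity
    are continuous across phase boundaries (the final state of one
    phase seeds the next).  The true boundary times are recorded in
    ``true_change_times``.
    """
    if not phases:
        raise ValueError("need at least one phase")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = _draw_initial_velocity(phases[0][0], v0, rng)
    state = np.array([z0[0], v[0], z0[1], v[1]])
    t_all, states_all = [], []
    t_start = 0.0
    change_times = []
    for j, (params, duration) in enumerate(phases):
        if duration <= 0:
            raise ValueError("phase durations must be positive")
        n_steps = max(1, int(round(duration / dt)))
        t = t_start + dt * np.arange(n_steps + 1)
        states = _simulate_states(params, t, state, rng)
        if j == 0:
            t_all.append(t)
            states_all.append(states)
        else:
            t_all.append(t[1:])
            states_all.append(states[1:])
        state = states[-1]
        t_start = t[-1]
        if j < len(phases) - 1:
            change_times.append(t_start)
    t = np.concatenate(t_all)
    s = np.concatenate(states_all, axis=0)
    return Track(
        t=t, x=s[:, 0], y=s[:, 2], vx=s[:, 1], vy=s[:, 3],
        true_change_times=np.array(change_times),
    )


def subsample_random(track: Track, n: int, seed: int | np.random.Generator | None = None) -> Track:
    """Randomly subsample ``n`` points (always keeping the first), time-sorted."""
    m = len(track)
    if not (2 <= n <= m):
        raise ValueError(f"n must be in [2, {m}], got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keep = rng.choice(np.arange(1, m), size=n - 1, replace=False)
    idx = np.sort(np.concatenate([[0], keep]))
    return Track(
        t=track.t[idx], x=track.x[idx], y=track.y[idx],
        vx=None if track.vx is None else np.asarray(track.vx)[idx],
        vy=None if track.vy is None else np.asarray(track.vy)[idx],
        true_change_times=track.true_change_times,
    )


def irregular_times(
    n: int,
    *,
    distribution: str = "lognormal",
    mean_gap: float = 34.5 / 60.0,
    median_gap: float = 23.0 / 60.0,
    min_gap: float | None = 6.0 / 60.0,
    max_gap: float | None = 10.0,
    t0: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n`` sample times with irregular gaps.

    Defaults emulate marine GPS telemetry of the kind produced by a
    surfacing whale: lognormal gaps with mean 34.5 min and median
    23 min, truncated to [6 min, 10 h], expressed in hours.  The
    lognormal (mu, sigma) are solved from the mean/median pair
    (median = e^mu, mean = e^{mu + sigma^2/2}); gaps outside the
    truncation range are clipped.

    ``distribution="constant"`` yields a regular grid with gap
    ``mean_gap``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if distribution == "constant":
        if mean_gap <= 0:
            raise ValueError("mean_gap must be positive")
        return t0 + mean_gap * np.arange(n)
    if distribution != "lognormal":
        raise ValueError(f"unknown gap distribution {distribution!r}")
    if not (mean_gap >= median_gap > 0):
        raise ValueError("lognormal gaps require mean_gap >= median_gap > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = math.log(median_gap)
    sigma = math.sqrt(2.0 * math.log(mean_gap / median_gap))
    gaps = rng.lognormal(mean=mu, sigma=sigma, size=n - 1)
    lo = 0.0 if min_gap is None else min_gap
    hi = np.inf if max_gap is None else max_gap
    gaps = np.clip(gaps, lo, hi)
    return t0 + np.concatenate([[0.0], np.cumsum(gaps)])


def whale_like_times(n: int = 954, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Irregular sample times (hours) mimicking sparse marine telemetry."""
    return irregular_times(n, seed=seed)
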