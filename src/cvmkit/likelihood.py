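"""Likelihood functions for CVM models on irregularly sampled tracks.

Two likelihoods are provided:

* the **velocity likelihood**, built on finite-difference (or spline)
  velocity estimates, whose conditional transitions are Gaussian with a
  complex-exponential decay ``exp(-(1/tau + i omega) dt)`` — fast, and
  accurate when sampling is dense relative to tau;
* the **full-position likelihood**, the joint Gaussian density of all
  observed locations given a stationary initial state conditioned on the
  first position.  It is evaluated either densely (explicit joint
  covariance, O(n^2)) or with a Kalman filter (O(n)); the two agree to
  numerical precision and the filter is the practical route.

Positions and velocities are handled internally as complex numbers
z = x + iy.  Because the driving noise is circularly symmetric, every
covariance in the filter is a real scalar and every gain a complex
scalar, which keeps the per-step cost trivial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve

from .models import CVMParams, ModelKind, complex_transition, transition
from .simulate import Track

__all__ = [
    "VelocitySeries",
    "velocities_from_track",
    "velocity_loglik",
    "position_loglik",
    "profile_velocity_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class VelocitySeries:
    """Velocity estimates along a track.

    ``t_mid`` are the times the estimates refer to (interval midpoints
    for finite differences, observation times for splines), ``v`` the
    2-D velocity estimates and ``dt`` the interval each estimate spans.
    """

    t_mid: np.ndarray
    v: np.ndarray
    dt: np.ndarray

    @property
    def v_complex(self) -> np.ndarray:
        return self.v[:, 0] + 1j * self.v[:, 1]

    def __len__(self) -> int:
        return len(self.t_mid)


def velocities_from_track(track: Track, method: str = "finite_difference") -> VelocitySeries:
    """Estimate velocities from positions.

    ``finite_difference`` uses V_i = (Z_i - Z_{i-1}) / (T_i - T_{i-1}),
    placed at interval midpoints.  ``spline`` differentiates an
    interpolating cubic of x(t) and y(t) at the observation times,
    which reduces the chord-shortening bias of finite differences on
    curved paths.
    """
    t, x, y = track.t, track.x, track.y
    if len(t) < 3:
        raise ValueError("need at least 3 positions to estimate velocities")
    dt = np.diff(t)
    if method == "finite_difference":
        vx = np.diff(x) / dt
        vy = np.diff(y) / dt
        return VelocitySeries(t_mid=(t[:-1] + t[1:]) / 2.0, v=np.column_stack([vx, vy]), dt=dt)
    if method == "spline":
        sx = CubicSpline(t, x)
        sy = CubicSpline(t, y)
        v = np.column_stack([sx(t, 1), sy(t, 1)])
        full_dt = np.concatenate([[dt[0]], (dt[:-1] + dt[1:]) / 2.0, [dt[-1]]])
        return VelocitySeries(t_mid=t.copy(), v=v, dt=full_dt)
    raise ValueError(f"unknown velocity method {method!r}")


# ---------------------------------------------------------------------
# velocity likelihood
# ---------------------------------------------------------------------


def _velocity_terms(tau: float, omega: float, v: np.ndarray, t_mid: np.ndarray):
    """Per-observation ingredients of the velocity likelihood.

    Returns arrays ``(b, c, g)`` over all len(v) terms: residual bases
    b_i, advective-design coefficients c_i and relative per-component
    variances g_i (so Var = eta^2 g_i), with the first velocity scored
    under the stationary law (g = 1/2).
    """
    d = np.diff(t_mid)
    a = complex(1.0 / tau, omega)
    G = np.exp(-a * d)
    g_pairs = -np.expm1(-2.0 * d / tau) / 2.0
    b = np.empty(len(v), dtype=complex)
    c = np.empty(len(v), dtype=complex)
    g = np.empty(len(v))
    b[0], c[0], g[0] = v[0], 1.0, 0.5
    b[1:] = v[1:] - G * v[:-1]
    c[1:] = 1.0 - G
    g[1:] = g_pairs
    return b, c, g


def velocity_loglik(params: CVMParams, vs: VelocitySeries) -> float:
    """Log-likelihood of a velocity series under a CVM.

    The conditional law of v_i given v_{i-1} is an isotropic Gaussian
    with mean mu + exp(-(1/tau + i omega) dt) (v_{i-1} - mu) and
    per-component variance (eta^2/2)(1 - exp(-2 dt/tau)); the first
    velocity is scored under the stationary law N(mu, (eta^2/2) I).
    Returns -inf for invalid parameter values so optimizers can probe
    freely.
    """
    if len(vs) == 0:
        raise ValueError("empty velocity series")
    if not (params.tau > 0 and params.eta > 0):
        return -math.inf
    b, c, g = _velocity_terms(params.tau, params.omega, vs.v_complex, vs.t_mid)
    r = b - c * params.mu_complex
    s2 = params.eta**2 * g
    return float(-np.sum(np.log(2.0 * math.pi * s2)) - np.sum(np.abs(r) ** 2 / (2.0 * s2)))


def _profile_loglik(tau, omega, v, t_mid, advective):
    """Velocity log-likelihood profiled over mu (WLS) and eta (scale)."""
    b, c, g = _velocity_terms(tau, omega, v, t_mid)
    if advective:
        w = 1.0 / g
        denom = np.sum(np.abs(c) ** 2 * w)
        mu = np.sum(np.conj(c) * b * w) / denom
    else:
        mu = 0.0j
    r = b - c * mu
    n = len(v)
    quad = float(np.sum(np.abs(r) ** 2 / g))
    eta2 = quad / (2.0 * n)
    if eta2 <= 0:
        return -math.inf, mu, 0.0
    ll = -n * math.log(2.0 * math.pi) - n * math.log(eta2) - float(np.sum(np.log(g))) - n
    return ll, mu, math.sqrt(eta2)


def profile_velocity_fit(
    vs: VelocitySeries,
    kind: ModelKind | str,
    *,
    n_tau: int = 24,
    n_omega: int = 15,
    refine: bool = True,
) -> tuple[CVMParams, float]:
    """Fast velocity-likelihood fit with mu and eta profiled out.

    Only tau (and omega, for rotational kinds) require numerical
    search: mu enters the residuals linearly (weighted least squares)
    and eta is a pure scale.  The search is a log-spaced tau grid
    (crossed with an omega grid for rotational kinds) followed by an
    optional Nelder-Mead refinement.  Used to initialize the full
    maximum-likelihood fits and as the workhorse of the change-point
    sweep.
    """
    from scipy.optimize import minimize

    kind = ModelKind.coerce(kind)
    v = vs.v_complex
    t_mid = vs.t_mid
    dts = np.diff(t_mid)
    lo = max(np.min(dts) / 4.0, 1e-12)
    hi = (t_mid[-1] - t_mid[0]) * 4.0
    taus = np.geomspace(lo, hi, n_tau)
    advective = kind in (ModelKind.ACVM, ModelKind.RACVM)
    rotational = kind in (ModelKind.RCVM, ModelKind.RACVM)
    if rotational:
        w_max = math.pi / max(np.median(dts), 1e-12)
        omegas = np.concatenate([-np.geomspace(w_max, w_max / 100, n_omega // 2),
                                 [0.0],
                                 np.geomspace(w_max / 100, w_max, n_omega // 2)])
    else:
        omegas = np.array([0.0])
    best = (-math.inf, taus[0], 0.0)
    for tau in taus:
        for om in omegas:
            ll, _, _ = _profile_loglik(tau, om, v, t_mid, advective)
            if ll > best[0]:
                best = (ll, tau, om)
    ll, tau, om = best
    if refine:
        if rotational:
            def neg(p):
                l, _, _ = _profile_loglik(math.exp(p[0]), p[1], v, t_mid, advective)
                return -l
            res = minimize(neg, [math.log(tau), om], method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 300})
            tau, om = math.exp(res.x[0]), float(res.x[1])
            ll = -res.fun
        else:
            def neg1(p):
                l, _, _ = _profile_loglik(math.exp(p[0]), 0.0, v, t_mid, advective)
                return -l
            res = minimize(neg1, [math.log(tau)], method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200})
            tau = math.exp(res.x[0])
            ll = -res.fun
    _, mu, eta = _profile_loglik(tau, om if rotational else 0.0, v, t_mid, advective)
    params = CVMParams(
        kind=kind, tau=tau, eta=max(eta, 1e-12),
        mu=(mu.real, mu.imag) if advective else (0.0, 0.0),
        omega=om if rotational else 0.0,
    )
    return params, ll


# ---------------------------------------------------------------------
# position likelihood
# ---------------------------------------------------------------------


def _transition_coeffs(params: CVMParams, dts: np.ndarray):
    """Vectorized complex transition ingredients for an array of intervals.

    Returns arrays (h, G, c_zz, c_zu, c_uu) matching
    :func:`cvmkit.models.complex_transition` elementwise, with the same
    short-interval series branch.
    """
    tau, eta, omega = params.tau, params.eta, params.omega
    a = complex(1.0 / tau, omega)
    aT = a * dts
    G = np.exp(-aT)
    h = (1.0 - G) / a
    two_q = 2.0 * eta * eta / tau
    em2 = -np.expm1(-2.0 * dts / tau)
    c_uu = eta * eta * em2
    ac = a.conjugate()
    Gc = np.conj(G)
    with np.errstate(invalid="ignore"):
        inv_a2 = 1.0 / (a * ac).real
        int_h2 = inv_a2 * (dts - (1.0 - G) / a - (1.0 - Gc) / ac + (tau / 2.0) * em2).real
        int_hca = (1.0 / a) * ((1.0 - Gc) / ac - (tau / 2.0) * em2)
    small = np.abs(aT) < 1e-3
    if np.any(small):
        d = dts[small]
        a2 = a * a
        abs_a2 = (a * ac).real
        int_h2_s = d**3 / 3.0 - a.real * d**4 / 4.0 + (abs_a2 / 4.0 + a2.real / 3.0) * d**5 / 5.0
        int_hca_s = (d**2 / 2.0
                     - (a / 2.0 + ac) * d**3 / 3.0
                     + (a2 / 6.0 + abs_a2 / 2.0 + ac**2 / 2.0) * d**4 / 4.0)
        int_h2 = np.where(small, 0.0, int_h2)
        int_hca = np.where(small, 0.0, int_hca)
        int_h2[small] = int_h2_s
        int_hca[small] = int_hca_s
    return h, G, two_q * int_h2, two_q * int_hca, c_uu


def _kalman_core_py(z, h, G, c_zz, c_zu, c_uu, dmh, mu, eta2):
    m = mu
    P = eta2
    ll = 0.0
    for k in range(len(h)):
        hk, Gk = h[k], G[k]
        z_pred = z[k] + dmh[k] * mu + hk * m
        v_pred = mu + Gk * (m - mu)
        h2 = hk.real * hk.real + hk.imag * hk.imag
        S = h2 * P + c_zz[k]
        if not (S > 0.0) or not math.isfinite(S):
            return -math.inf
        C_zv = hk * Gk.conjugate() * P + c_zu[k]
        e = z[k + 1] - z_pred
        ll += -math.log(math.pi * S) - (e.real * e.real + e.imag * e.imag) / S
        m = v_pred + (C_zv.conjugate() / S) * e
        czv2 = C_zv.real * C_zv.real + C_zv.imag * C_zv.imag
        G2 = Gk.real * Gk.real + Gk.imag * Gk.imag
        P = G2 * P + c_uu[k] - czv2 / S
        if P < 0.0:
            P = 0.0
    return ll


try:  # the filter loop is scalar and sequential: JIT it when available
    from numba import njit as _njit

    _kalman_core = _njit(cache=True, fastmath=False)(_kalman_core_py)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _kalman_core = _kalman_core_py


def _kalman_loglik(params: CVMParams, t: np.ndarray, z: np.ndarray) -> float:
    """Kalman-filter position log-likelihood in complex scalars.

    The filter conditions on z(0) at the first observed position with a
    stationary velocity prior; positions are observed without error, so
    the filtered state reduces to the velocity with a single real
    variance P (the driving noise is circularly symmetric, making every
    filter quantity a complex or real scalar).
    """
    dts = np.diff(t)
    h, G, c_zz, c_zu, c_uu = _transition_coeffs(params, dts)
    dmh = dts - h
    return float(
        _kalman_core(
            np.ascontiguousarray(z, dtype=np.complex128),
            np.ascontiguousarray(h), np.ascontiguousarray(G),
            np.ascontiguousarray(c_zz), np.ascontiguousarray(c_zu),
            np.ascontiguousarray(c_uu), np.ascontiguousarray(dmh),
            complex(params.mu_complex), float(params.eta**2),
        )
    )


def _dense_loglik(params: CVMParams, t: np.ndarray, z: np.ndarray) -> float:
    """Dense full-position log-likelihood via the explicit joint covariance.

    Builds the joint Gaussian of positions 2..n by accumulating the
    exact state transitions; O(n^2) blocks, intended for moderate n and
    as the reference for the Kalman route.
    """
    n = len(t)
    mu = params.mu_complex
    # state mean / covariance recursion on (x, vx, y, vy)
    m = np.array([z[0].real, mu.real, z[0].imag, mu.imag])
    P = np.diag([0.0, params.eta**2 / 2.0, 0.0, params.eta**2 / 2.0])
    means = []
    covs = {}  # (j, k) -> Cov(s_j, s_k), j <= k, over states 1..n-1 (0-based obs index)
    cross: list[np.ndarray] = []  # Cov(s_j, s_current) for j < current
    st_cache: dict[float, object] = {}
    for k in range(1, n):
        d = float(t[k] - t[k - 1])
        st = st_cache.get(d)
        if st is None:
            st = transition(params, d)
            st_cache[d] = st
        T, drift, Q = st.transition, st.drift, st.noise_cov
        m = T @ m + drift
        cross = [C @ T.T for C in cross]
        P = T @ P @ T.T + Q
        means.append(m.copy())
        for j, C in enumerate(cross):
            covs[(j, k - 1)] = C
        covs[(k - 1, k - 1)] = P
        cross = cross + [P]
    # observed coordinates: (x, y) rows of each state
    idx = [0, 2]
    N = n - 1
    mean_vec = np.concatenate([mm[idx] for mm in means])
    Sigma = np.zeros((2 * N, 2 * N))
    for (j, k), C in covs.items():
        block = C[np.ix_(idx, idx)]
        Sigma[2 * j : 2 * j + 2, 2 * k : 2 * k + 2] = block
        if j != k:
            Sigma[2 * k : 2 * k + 2, 2 * j : 2 * j + 2] = block.T
    obs = np.concatenate([[z[k].real, z[k].imag] for k in range(1, n)])
    r = obs - mean_vec
    try:
        cf = cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(Sigma) / (2 * N)
        logger.info("dense position covariance near-singular; adding jitter %g", jitter)
        Sigma = Sigma + jitter * np.eye(2 * N)
        cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = float(r @ cho_solve(cf, r))
    return float(-0.5 * (2 * N * math.log(2.0 * math.pi) + logdet + quad))


def position_loglik(params: CVMParams, track: Track, method: str = "kalman") -> float:
    """Full-position log-likelihood of a track under a CVM.

    The joint Gaussian density of all positions after the first, given
    a stationary initial state centered on the first position.
    ``method="kalman"`` (default) is O(n); ``method="dense"`` builds the
    explicit joint covariance and serves as a reference implementation.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 positions for the position likelihood")
    z = track.x + 1j * track.y
    if method == "kalman":
        return _kalman_loglik(params, track.t, z)
    if method == "dense":
        return _dense_loglik(params, track.t, z)
    raise ValueError(f"unknown position likelihood method {method!r}")
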