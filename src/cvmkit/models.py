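"""Core definitions of the correlated velocity movement (CVM) model family.

A CVM describes a planar track z(t) as the time-integral of a velocity
process v(t) that follows a (possibly rotating, possibly advective)
Ornstein-Uhlenbeck stochastic differential equation,

    dv = A (mu - v) dt + (eta / sqrt(tau)) dw_t,

where ``A`` couples the relaxation rate 1/tau with an angular speed omega,

    A = [[1/tau, -omega], [omega, 1/tau]].

The family has four nested members distinguished by which of the drift
(mu) and rotation (omega) terms are active:

============  =========================  ==========
kind          free parameters            count
============  =========================  ==========
UCVM          tau, eta                   2
ACVM          tau, eta, mu_x, mu_y       4
RCVM          tau, eta, omega            3
RACVM         tau, eta, mu, omega        5
============  =========================  ==========

Parameters are biologically interpretable: ``tau`` is the characteristic
time scale of velocity autocorrelation (tau -> 0 gives Brownian motion,
tau -> infinity straight-line motion), ``eta`` the root-mean-squared
random speed, ``mu`` the advective (drift) velocity and ``omega`` the
mean angular speed in radians per unit time.

This module provides the parameter container, unit conversions,
stationary moments, theoretical velocity autocovariance functions and
the exact per-interval linear-Gaussian state transition shared by the
simulator and the likelihoods.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.linalg import expm
from scipy.special import i0e, i1e

__all__ = [
    "ModelKind",
    "CVMParams",
    "StateTransition",
    "N_PARAMS",
    "speed_conversions",
    "nu_to_eta",
    "eta_to_nu",
    "stationary_moments",
    "rice_mean",
    "theoretical_vaf",
    "transition",
    "transition_van_loan",
    "complex_transition",
    "johnson_map",
    "johnson_inverse",
    "rotation_scale",
]


class ModelKind(str, Enum):
    """The four members of the CVM family."""

    UCVM = "ucvm"
    ACVM = "acvm"
    RCVM = "rcvm"
    RACVM = "racvm"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


#: number of free parameters per model kind (enters AIC/BIC and the
#: change-point parameter accounting)
N_PARAMS: dict[ModelKind, int] = {
    ModelKind.UCVM: 2,
    ModelKind.ACVM: 4,
    ModelKind.RCVM: 3,
    ModelKind.RACVM: 5,
}

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class CVMParams:
    """Parameter set of one CVM model.

    Parameters
    ----------
    kind:
        Model kind; constrains which of ``mu`` and ``omega`` may be
        nonzero.
    tau:
        Characteristic time scale of velocity autocorrelation (> 0).
    eta:
        Root-mean-squared random speed (> 0); ``eta**2`` is the
        stationary mean squared speed of the random velocity component
        (summed over both coordinates).
    mu:
        Advective velocity ``(mu_x, mu_y)``; must be ``(0, 0)`` for
        UCVM and RCVM.
    omega:
        Mean angular speed (radians / time); must be 0 for UCVM and
        ACVM.  Following the SDE sign convention, positive ``omega``
        rotates the velocity clockwise when the y-axis points up.
    """

    kind: ModelKind
    tau: float
    eta: float
    mu: tuple[float, float] = (0.0, 0.0)
    omega: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModelKind.coerce(self.kind))
        object.__setattr__(self, "tau", float(self.tau))
        object.__setattr__(self, "eta", float(self.eta))
        object.__setattr__(self, "mu", (float(self.mu[0]), float(self.mu[1])))
        object.__setattr__(self, "omega", float(self.omega))
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.eta > 0):
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.kind in (ModelKind.UCVM, ModelKind.RCVM) and self.mu != (0.0, 0.0):
            raise ValueError(f"{self.kind.value} requires mu=(0,0), got {self.mu}")
        if self.kind in (ModelKind.UCVM, ModelKind.ACVM) and self.omega != 0.0:
            raise ValueError(f"{self.kind.value} requires omega=0, got {self.omega}")

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.kind]

    @property
    def mu_complex(self) -> complex:
        return complex(self.mu[0], self.mu[1])

    @property
    def nu(self) -> float:
        """Mean tangential speed of the *random* component, (sqrt(pi)/2) eta."""
        return eta_to_nu(self.eta)

    # -- flat-record serialization -------------------------------------
    def to_record(self) -> dict[str, float | str]:
        """Flat key-value form (JSON/CSV row); bit-exact round trip."""
        return {
            "kind": self.kind.value,
            "tau": self.tau,
            "eta": self.eta,
            "mu_x": self.mu[0],
            "mu_y": self.mu[1],
            "omega": self.omega,
        }

    @classmethod
    def from_record(cls, rec: Mapping[str, float | str]) -> "CVMParams":
        return cls(
            kind=ModelKind.coerce(rec["kind"]),
            tau=float(rec["tau"]),
            eta=float(rec["eta"]),
            mu=(float(rec.get("mu_x", 0.0)), float(rec.get("mu_y", 0.0))),
            omega=float(rec.get("omega", 0.0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_record(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "CVMParams":
        return cls.from_record(json.loads(s))


def speed_conversions(value: float, direction: str) -> float:
    """Convert between the rms random speed eta and the mean speed nu.

    For unbiased motion the speed is Rayleigh distributed, giving the
    exact relation eta = 2 nu / sqrt(pi).

    Parameters
    ----------
    value:
        Positive speed to convert.
    direction:
        ``"nu_to_eta"`` or ``"eta_to_nu"``.
    """
    if not (value > 0):
        raise ValueError(f"speed must be positive, got {value}")
    if direction == "nu_to_eta":
        return 2.0 * value / _SQRT_PI
    if direction == "eta_to_nu":
        return _SQRT_PI * value / 2.0
    raise ValueError(f"unknown direction {direction!r}")


def nu_to_eta(nu: float) -> float:
    return speed_conversions(nu, "nu_to_eta")


def eta_to_nu(eta: float) -> float:
    return speed_conversions(eta, "eta_to_nu")


def rice_mean(sigma: float, offset: float) -> float:
    """Mean of the magnitude of a 2-D Gaussian vector.

    The vector has independent components with standard deviation
    ``sigma`` and mean vector of length ``offset`` (a Rice
    distribution).  Uses exponentially scaled Bessel functions for
    numerical stability at large offsets.
    """
    if sigma == 0.0:
        return abs(offset)
    x = offset * offset / (2.0 * sigma * sigma)
    # Laguerre L_{1/2}(-x) = e^{-x/2} [(1+x) I0(x/2) + x I1(x/2)];
    # with scaled Bessels the e^{-x/2} cancels.
    lag = (1.0 + x) * i0e(x / 2.0) + x * i1e(x / 2.0)
    return sigma * math.sqrt(math.pi / 2.0) * lag


def stationary_moments(params: CVMParams) -> dict[str, float]:
    """Stationary mean speed and mean squared speed of the process.

    The stationary velocity is an isotropic 2-D Gaussian with mean
    ``mu`` and per-component variance ``eta**2 / 2``, so the mean
    squared speed decomposes as eta^2 + |mu|^2 and the mean speed is
    the corresponding Rice mean (reducing to nu = (sqrt(pi)/2) eta
    when mu = 0).
    """
    mu_norm = math.hypot(*params.mu)
    sigma = params.eta / math.sqrt(2.0)
    return {
        "mean_speed": rice_mean(sigma, mu_norm),
        "mean_sq_speed": params.eta**2 + mu_norm**2,
    }


def theoretical_vaf(params: CVMParams, lags: Iterable[float]) -> np.ndarray:
    """Theoretical velocity autocovariance function at the given lags.

    VAF(dt) = |mu|^2 + eta^2 exp(-dt/tau) cos(omega dt): an exponential
    decay from eta^2 + |mu|^2 at lag 0 to the advective asymptote
    |mu|^2, with an oscillation at frequency omega for rotational
    models.
    """
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be nonnegative")
    mu2 = params.mu[0] ** 2 + params.mu[1] ** 2
    return mu2 + params.eta**2 * np.exp(-lags / params.tau) * np.cos(params.omega * lags)


def johnson_map(params: CVMParams) -> dict[str, float]:
    """Map (tau, eta) to the continuous-time CRW parameterization.

    The Kalman-filter telemetry literature writes the velocity SDE with
    an autocorrelation parameter beta and a white-noise variance
    sigma^2; these correspond to 1/tau and eta^2/tau respectively.
    """
    return {"beta_J": 1.0 / params.tau, "sigma2_J": params.eta**2 / params.tau}


def johnson_inverse(beta_J: float, sigma2_J: float) -> tuple[float, float]:
    """Recover (tau, eta) from (beta_J, sigma2_J)."""
    tau = 1.0 / beta_J
    return tau, math.sqrt(sigma2_J * tau)


def rotation_scale(params: CVMParams) -> float:
    """Characteristic spatial scale of rotation, rho = eta / |omega|.

    An analogue of the circling radius of soaring flight.  Undefined
    for non-rotational models.
    """
    if params.omega == 0.0:
        raise ValueError("rotation scale is undefined for omega = 0")
    return params.eta / abs(params.omega)


# ---------------------------------------------------------------------
# Exact per-interval state transition
# ---------------------------------------------------------------------

#: state vector ordering used throughout: (x, vx, y, vy)
STATE_ORDER = ("x", "vx", "y", "vy")


@dataclass(frozen=True)
class StateTransition:
    """Exact linear-Gaussian transition of the state (x, vx, y, vy) over dt.

    ``s(t + dt) = transition @ s(t) + drift + e``, with
    ``e ~ N(0, noise_cov)``.  ``drift`` carries the advective
    contribution of mu.
    """

    dt: float
    transition: np.ndarray
    drift: np.ndarray
    noise_cov: np.ndarray


def complex_transition(params: CVMParams, dt: float) -> tuple[complex, complex, float, complex, float]:
    """Complex-scalar ingredients of the exact transition over ``dt``.

    Writing positions and velocities as complex numbers z = x + iy,
    v = vx + i vy, the centered velocity u = v - mu evolves as
    u(t+dt) = G u(t) + noise with G = exp(-a dt), a = 1/tau + i omega,
    and the position picks up h(dt) u(t) with h = (1 - G)/a.  The
    driving noise is circularly symmetric, so the joint innovation of
    (z, v) is fully described by the Hermitian (co)variances

        c_zz = E|zeta|^2,  c_zu = E[zeta conj(u_n)],  c_uu = E|u_n|^2

    (each the *total* variance over both real coordinates).

    Returns ``(h, G, c_zz, c_zu, c_uu)``.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    tau, eta, omega = params.tau, params.eta, params.omega
    a = complex(1.0 / tau, omega)
    aT = a * dt
    G = cmath.exp(-aT)
    h = (1.0 - G) / a
    two_q = 2.0 * eta * eta / tau  # total (2-component) white-noise intensity
    # c_uu = two_q * int_0^dt |e^{-a s}|^2 ds, |e^{-a s}|^2 = e^{-2s/tau}
    em2 = -math.expm1(-2.0 * dt / tau)  # 1 - e^{-2 dt/tau}, stable
    c_uu = eta * eta * em2
    if abs(aT) < 1e-3:
        # series branch: the closed forms below cancel catastrophically
        # for dt << tau
        a2 = a * a
        abs_a2 = (a * a.conjugate()).real
        int_h2 = dt**3 / 3.0 - (a.real) * dt**4 / 4.0 + (abs_a2 / 4.0 + a2.real / 3.0) * dt**5 / 5.0
        int_hca = (
            dt**2 / 2.0
            - (a / 2.0 + a.conjugate()) * dt**3 / 3.0
            + (a2 / 6.0 + abs_a2 / 2.0 + a.conjugate() ** 2 / 2.0) * dt**4 / 4.0
        )
    else:
        ac = a.conjugate()
        Gc = G.conjugate()
        inv_a2 = 1.0 / (a * ac).real
        int_h2 = inv_a2 * (dt - (1.0 - G) / a - (1.0 - Gc) / ac + (tau / 2.0) * em2).real
        int_hca = (1.0 / a) * ((1.0 - Gc) / ac - (tau / 2.0) * em2)
    c_zz = two_q * int_h2
    c_zu = two_q * int_hca
    return h, G, float(c_zz), c_zu, float(c_uu)


def _complex_to_real_cov(c_zz: float, c_zu: complex, c_uu: float) -> np.ndarray:
    """4x4 real covariance on (x, vx, y, vy) from circular complex (co)variances."""
    q = np.zeros((4, 4))
    # indices: x=0, vx=1, y=2, vy=3;  z = x + iy, u = vx + i vy
    q[0, 0] = q[2, 2] = c_zz / 2.0
    q[1, 1] = q[3, 3] = c_uu / 2.0
    re, im = c_zu.real / 2.0, c_zu.imag / 2.0
    # Cov(Re z, Re u) = Cov(Im z, Im u) = Re(c_zu)/2
    q[0, 1] = q[1, 0] = re
    q[2, 3] = q[3, 2] = re
    # Cov(Im z, Re u) = Im(c_zu)/2 ; Cov(Re z, Im u) = -Im(c_zu)/2
    q[2, 1] = q[1, 2] = im
    q[0, 3] = q[3, 0] = -im
    return q


def _complex_mult_block(c: complex) -> np.ndarray:
    """2x2 real matrix of multiplication by the complex scalar c on (Re, Im)."""
    return np.array([[c.real, -c.imag], [c.imag, c.real]])


def transition(params: CVMParams, dt: float) -> StateTransition:
    """Exact transition of (x, vx, y, vy) over an interval ``dt``.

    The velocity block is exp(-dt/tau) times a rotation by -omega*dt;
    the position block integrates the velocity exactly; ``noise_cov``
    is the exact integrated-OU innovation covariance.  Shared by the
    simulator and all likelihoods, so neither carries discretization
    bias at any dt.
    """
    h, G, c_zz, c_zu, c_uu = complex_transition(params, dt)
    T = np.zeros((4, 4))
    Hb = _complex_mult_block(h)
    Gb = _complex_mult_block(G)
    # rows/cols (x, y) at 0,2 and (vx, vy) at 1,3
    T[np.ix_([0, 2], [0, 2])] = np.eye(2)
    T[np.ix_([0, 2], [1, 3])] = Hb
    T[np.ix_([1, 3], [1, 3])] = Gb
    mu = params.mu_complex
    dz = (dt - h) * mu
    dv = (1.0 - G) * mu
    drift = np.array([dz.real, dv.real, dz.imag, dv.imag])
    return StateTransition(dt=float(dt), transition=T, drift=drift, noise_cov=_complex_to_real_cov(c_zz, c_zu, c_uu))


def transition_van_loan(params: CVMParams, dt: float) -> StateTransition:
    """Transition computed by brute-force matrix exponentials.

    Independent construction used to cross-check :func:`transition`:
    the deterministic part comes from the exponential of the augmented
    (state + constant) generator and the noise covariance from the Van
    Loan block-matrix exponential.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    tau, eta, omega = params.tau, params.eta, params.omega
    mx, my = params.mu
    # generator F on (x, vx, y, vy); affine term b from mu
    F = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [0.0, -1.0 / tau, 0.0, omega],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, -omega, 0.0, -1.0 / tau],
        ]
    )
    b = np.array([0.0, mx / tau - omega * my, 0.0, my / tau + omega * mx])
    aug = np.zeros((5, 5))
    aug[:4, :4] = F
    aug[:4, 4] = b
    E = expm(aug * dt)
    T, drift = E[:4, :4], E[:4, 4]
    # Van Loan: expm([[-F, GG'], [0, F']] dt) -> Q = Phi' * (upper right)
    g2 = eta * eta / tau
    GG = np.diag([0.0, g2, 0.0, g2])
    M = np.zeros((8, 8))
    M[:4, :4] = -F
    M[:4, 4:] = GG
    M[4:, 4:] = F.T
    EM = expm(M * dt)
    Q = EM[4:, 4:].T @ EM[:4, 4:]
    Q = (Q + Q.T) / 2.0
    return StateTransition(dt=float(dt), transition=T, drift=drift, noise_cov=Q)
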