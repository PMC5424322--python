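"""Maximum-likelihood and moment estimation of CVM parameters.

The central entry point is :class:`CVMFitter`, a scikit-learn style
estimator: construct with a model kind and likelihood method, call
``fit`` on a track, and read the fitted parameters, confidence
intervals and information criteria from trailing-underscore
attributes.  ``fit_cvm``, ``select_model`` and ``subsample_stability``
are thin functional wrappers.

tau and eta are optimized on the log scale; confidence intervals come
from the inverse observed information on that working scale and are
back-transformed, which respects positivity and the right-skew of
their sampling distributions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess3

from .models import (
    CVMParams,
    ModelKind,
    N_PARAMS,
    eta_to_nu,
    stationary_moments,
)
from .likelihood import (
    position_loglik,
    profile_velocity_fit,
    velocities_from_track,
    velocity_loglik,
)
from .simulate import Track, subsample_random

__all__ = [
    "FitResult",
    "CVMFitter",
    "fit_cvm",
    "select_model",
    "subsample_stability",
    "CRWSummary",
    "crw_summary",
    "crw_match",
    "as_track",
]

logger = logging.getLogger(__name__)

ALL_KINDS = (ModelKind.UCVM, ModelKind.ACVM, ModelKind.RCVM, ModelKind.RACVM)


def as_track(X) -> Track:
    """Coerce a Track, DataFrame with t/x/y columns, or (n, 3) array."""
    if isinstance(X, Track):
        return X
    if isinstance(X, pd.DataFrame):
        return Track(t=X["t"].to_numpy(float), x=X["x"].to_numpy(float), y=X["y"].to_numpy(float))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected a Track, a DataFrame with columns t,x,y, or an (n, 3) array")
    return Track(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2])


@dataclass
class FitResult:
    """One model fitted to one data window."""

    params: CVMParams
    ci: dict[str, tuple[float, float]]
    loglik: float
    n_obs: int
    n_eff: int
    aic: float
    bic: float
    likelihood_method: str
    converged: bool = True
    notes: str = ""

    @property
    def kind(self) -> ModelKind:
        return self.params.kind

    @property
    def mean_speed(self) -> float:
        return stationary_moments(self.params)["mean_speed"]

    def to_record(self) -> dict:
        rec = dict(self.params.to_record())
        rec.update(
            nu=eta_to_nu(self.params.eta),
            mean_speed=self.mean_speed,
            loglik=self.loglik,
            n_obs=self.n_obs,
            n_eff=self.n_eff,
            aic=self.aic,
            bic=self.bic,
            likelihood_method=self.likelihood_method,
            converged=self.converged,
        )
        for name, (lo, hi) in self.ci.items():
            rec[f"{name}_lo"] = lo
            rec[f"{name}_hi"] = hi
        return rec


# -- working-scale parameterization ----------------------------------

def _param_names(kind: ModelKind) -> list[str]:
    names = ["tau", "eta"]
    if kind in (ModelKind.ACVM, ModelKind.RACVM):
        names += ["mu_x", "mu_y"]
    if kind in (ModelKind.RCVM, ModelKind.RACVM):
        names += ["omega"]
    return names


def _pack(params: CVMParams) -> np.ndarray:
    w = [math.log(params.tau), math.log(params.eta)]
    if params.kind in (ModelKind.ACVM, ModelKind.RACVM):
        w += [params.mu[0], params.mu[1]]
    if params.kind in (ModelKind.RCVM, ModelKind.RACVM):
        w += [params.omega]
    return np.array(w)


def _unpack(kind: ModelKind, w: np.ndarray) -> CVMParams | None:
    try:
        tau, eta = math.exp(w[0]), math.exp(w[1])
    except OverflowError:
        return None
    if not (np.isfinite(tau) and np.isfinite(eta) and tau > 0 and eta > 0):
        return None
    mu = (0.0, 0.0)
    omega = 0.0
    i = 2
    if kind in (ModelKind.ACVM, ModelKind.RACVM):
        mu = (float(w[i]), float(w[i + 1]))
        i += 2
    if kind in (ModelKind.RCVM, ModelKind.RACVM):
        omega = float(w[i])
    try:
        return CVMParams(kind=kind, tau=tau, eta=eta, mu=mu, omega=omega)
    except ValueError:
        return None


_CHI2_1 = {0.95: 3.841458820694124}


def _chi2_quantile(level: float) -> float:
    from scipy.stats import chi2

    return _CHI2_1.get(level) or float(chi2.ppf(level, 1))


def _profile_ci_1param(negloglik, w_opt, i, nll_min, level, max_span=14.0):
    """Profile-likelihood interval for working parameter i by LR inversion.

    Walks outward from the optimum, re-optimizing the remaining
    parameters at each fixed value (warm-started), until the profile
    log-likelihood drops by chi2_{1,level}/2, then bisects the
    crossing.  Returns working-scale bounds; an unbounded side returns
    +/-inf.
    """
    from scipy.optimize import minimize as _min

    drop = _chi2_quantile(level) / 2.0
    target = nll_min + drop
    rest = [j for j in range(len(w_opt)) if j != i]

    def prof(val, w_warm):
        if not rest:
            return negloglik(np.array([val])), w_warm
        def inner(wr):
            w = np.empty(len(w_opt))
            w[i] = val
            w[rest] = wr
            return negloglik(w)
        res = _min(inner, w_warm[rest], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200 * max(1, len(rest))})
        w = np.array(w_warm)
        w[i] = val
        w[rest] = res.x
        return float(res.fun), w

    bounds = []
    for sign in (-1.0, 1.0):
        step = 0.3
        x_in, f_in = w_opt[i], nll_min
        w_warm = np.array(w_opt)
        found = None
        while abs(x_in - w_opt[i]) < max_span:
            x_out = x_in + sign * step
            f_out, w_warm = prof(x_out, w_warm)
            if f_out > target:
                # bisect between x_in and x_out
                a, fa, b, fb = x_in, f_in, x_out, f_out
                for _ in range(20):
                    m = 0.5 * (a + b)
                    fm, w_warm = prof(m, w_warm)
                    if fm > target:
                        b, fb = m, fm
                    else:
                        a, fa = m, fm
                    if abs(b - a) < 1e-3:
                        break
                found = 0.5 * (a + b)
                break
            x_in, f_in = x_out, f_out
            step *= 1.6
        bounds.append(found if found is not None else sign * math.inf)
    return bounds[0], bounds[1]


def _information_cis(
    negloglik, w_opt: np.ndarray, kind: ModelKind, level: float
) -> tuple[dict[str, tuple[float, float]], bool]:
    """95% (by default) Wald intervals from the observed information."""
    from scipy.stats import norm

    names = _param_names(kind)
    zq = norm.ppf(0.5 + level / 2.0)
    ok = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess3(w_opt, negloglik)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        H = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess3(w_opt, negloglik)
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.abs(np.diag(cov)))
        except Exception:
            se = np.full(len(w_opt), np.nan)
        ok = False
    ci = {}
    for i, name in enumerate(names):
        lo, hi = w_opt[i] - zq * se[i], w_opt[i] + zq * se[i]
        if name in ("tau", "eta"):
            ci[name] = (math.exp(lo) if np.isfinite(lo) else np.nan,
                        math.exp(hi) if np.isfinite(hi) else np.nan)
        else:
            ci[name] = (float(lo), float(hi))
    return ci, ok


class CVMFitter(BaseEstimator):
    """Fit a correlated velocity movement model to a planar track.

    Parameters
    ----------
    kind:
        ``"ucvm"``, ``"acvm"``, ``"rcvm"``, ``"racvm"`` or ``"auto"``
        (fit all ``candidates`` and keep the best by ``criterion``).
    likelihood:
        ``"kalman"`` (full-position likelihood via the Kalman filter,
        default), ``"dense"`` (same likelihood, explicit covariance) or
        ``"velocity"`` (finite-difference velocity likelihood; fast,
        best for dense sampling).
    criterion:
        ``"bic"`` (default) or ``"aic"``; used when ``kind="auto"``.
    candidates:
        Model kinds searched when ``kind="auto"``; defaults to all four.
    ci_level:
        Confidence level of the Wald intervals (default 0.95).

    Attributes
    ----------
    params_ : CVMParams
        Point estimates of the selected model.
    result_ : FitResult
        Full fit record (estimates, CIs, log-likelihood, AIC/BIC).
    ci_, loglik_, aic_, bic_ :
        Convenience views of ``result_``.
    selection_table_ : pandas.DataFrame
        Per-candidate criterion table (only when ``kind="auto"``).
    """

    def __init__(self, kind="auto", likelihood="kalman", criterion="bic",
                 candidates=None, ci_level=0.95, ci_method="profile"):
        self.kind = kind
        self.likelihood = likelihood
        self.criterion = criterion
        self.candidates = candidates
        self.ci_level = ci_level
        self.ci_method = ci_method

    def fit(self, X, y=None):
        track = as_track(X)
        if str(self.kind).lower() == "auto":
            cands = self.candidates or ALL_KINDS
            table = select_model(track, cands, criterion=self.criterion,
                                 likelihood=self.likelihood, ci_level=self.ci_level,
                                 ci_method=self.ci_method)
            self.selection_table_ = table
            best = table.attrs["results"][table.index[0]]
            self.result_ = best
        else:
            self.result_ = fit_cvm(track, self.kind, likelihood=self.likelihood,
                                   ci_level=self.ci_level, ci_method=self.ci_method)
        self.params_ = self.result_.params
        self.ci_ = self.result_.ci
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of a track under the fitted parameters."""
        track = as_track(X)
        if self.result_.likelihood_method == "velocity":
            return velocity_loglik(self.params_, velocities_from_track(track))
        method = "dense" if self.result_.likelihood_method == "position_dense" else "kalman"
        return position_loglik(self.params_, track, method=method)


def _loglik_fn(track: Track, likelihood: str):
    if likelihood in ("kalman", "position_kalman"):
        return (lambda p: position_loglik(p, track, "kalman")), len(track) - 1, "position_kalman"
    if likelihood in ("dense", "position_dense"):
        return (lambda p: position_loglik(p, track, "dense")), len(track) - 1, "position_dense"
    if likelihood == "velocity":
        vs = velocities_from_track(track)
        return (lambda p: velocity_loglik(p, vs)), len(vs), "velocity"
    raise ValueError(f"unknown likelihood method {likelihood!r}")


def _starts(track: Track, kind: ModelKind) -> list[CVMParams]:
    """Multi-start initial values: velocity-profile, VAF-flavored, dispersed."""
    vs = velocities_from_track(track)
    starts: list[CVMParams] = []
    try:
        p0, _ = profile_velocity_fit(vs, kind)
        starts.append(p0)
    except Exception:  # degenerate windows: fall through to dispersed start
        p0 = None
    if p0 is not None:
        disp = CVMParams(kind=kind, tau=p0.tau * 3.0, eta=p0.eta * 1.5,
                         mu=p0.mu, omega=-p0.omega if p0.omega else 0.0)
        starts.append(disp)
    if not starts:
        speed = float(np.mean(np.abs(vs.v_complex)))
        dtm = float(np.mean(np.diff(track.t)))
        base = CVMParams(kind=kind, tau=max(dtm, 1e-6), eta=max(speed, 1e-6),
                         mu=(0.0, 0.0) if kind in (ModelKind.ACVM, ModelKind.RACVM) else (0.0, 0.0),
                         omega=0.1 if kind in (ModelKind.RCVM, ModelKind.RACVM) else 0.0)
        starts.append(base)
    return starts


def fit_cvm(
    track: Track,
    kind: ModelKind | str,
    likelihood: str = "kalman",
    *,
    ci_level: float = 0.95,
    ci_method: str = "profile",
    fast: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of one CVM kind to a track.

    ``fast=True`` uses a single (velocity-profile) starting point and a
    tighter iteration cap — appropriate inside sweeps and candidate
    tests where thousands of fits are made and each window is small.

    Optimizes (ln tau, ln eta, mu, omega) by Nelder-Mead from multiple
    starting points (a fast profiled velocity-likelihood fit plus a
    dispersed start with the rotation sign flipped).

    Confidence intervals: ``ci_method="profile"`` (default) inverts the
    likelihood-ratio statistic for tau and eta — whose sampling
    distributions are markedly skewed on short tracks, where Wald
    intervals undercover — and uses observed-information Wald
    intervals for mu and omega; ``"wald"`` uses Wald intervals
    throughout; ``"none"`` skips CIs (fast, e.g. inside sweeps).
    """
    track = as_track(track)
    kind = ModelKind.coerce(kind)
    if len(track) < 8:
        raise ValueError(f"need at least 8 positions to fit, got {len(track)}")
    ll_fn, n_eff, method_name = _loglik_fn(track, likelihood)

    def negloglik(w):
        p = _unpack(kind, w)
        if p is None:
            return 1e300
        v = ll_fn(p)
        return -v if np.isfinite(v) else 1e300

    starts = _starts(track, kind)
    if fast:
        # single start, loose tolerances: information-criterion
        # comparisons need the log-likelihood to ~1e-2, far coarser
        # than the full-fit tolerance
        starts = starts[:1]
        opts = {"xatol": 1e-3, "fatol": 1e-3, "maxiter": 100, "maxfev": None}
    else:
        opts = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400, "maxfev": None}
    best = None
    for start in starts:
        w0 = _pack(start)
        res = minimize(negloglik, w0, method="Nelder-Mead",
                       options={"xatol": opts["xatol"], "fatol": opts["fatol"],
                                "maxiter": opts["maxiter"] * len(w0),
                                "maxfev": opts["maxiter"] * len(w0)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e300:
        raise RuntimeError(f"all optimization starts failed for {kind.value}")
    params = _unpack(kind, best.x)
    loglik = -float(best.fun)
    k = N_PARAMS[kind]
    if ci_method == "none":
        ci, ci_ok = {}, True
    elif ci_method in ("wald", "profile"):
        ci, ci_ok = _information_cis(negloglik, best.x, kind, ci_level)
        if ci_method == "profile":
            for i, name in enumerate(("tau", "eta")):
                lo, hi = _profile_ci_1param(negloglik, best.x, i, float(best.fun), ci_level)
                ci[name] = (math.exp(lo) if np.isfinite(lo) else 0.0,
                            math.exp(hi) if np.isfinite(hi) else math.inf)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return FitResult(
        params=params,
        ci=ci,
        loglik=loglik,
        n_obs=len(track),
        n_eff=n_eff,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n_eff),
        likelihood_method=method_name,
        converged=bool(best.success) and ci_ok,
    )


def select_model(
    track: Track,
    candidates: Sequence[ModelKind | str] = ALL_KINDS,
    criterion: str = "bic",
    likelihood: str = "kalman",
    *,
    ci_level: float = 0.95,
    ci_method: str = "profile",
    fast: bool = False,
) -> pd.DataFrame:
    """Fit each candidate kind and rank by information criterion.

    Returns a DataFrame indexed by kind with columns ``criterion`` and
    ``delta`` (relative to the best); the full :class:`FitResult`
    objects are stored in ``.attrs["results"]``.  Ties below 1e-6 are
    broken toward the model with fewer parameters.  Per-candidate fit
    failures are logged and dropped; at least one candidate must
    survive.  Confidence intervals are computed only for the winning
    model (``ci_method="none"`` skips them entirely).
    """
    track = as_track(track)
    if criterion.lower() not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    crit = criterion.lower()
    if len(list(candidates)) == 0:
        raise ValueError("need at least one candidate kind")
    results: dict[ModelKind, FitResult] = {}
    for cand in candidates:
        ck = ModelKind.coerce(cand)
        try:
            results[ck] = fit_cvm(track, ck, likelihood=likelihood,
                                  ci_level=ci_level, ci_method="none", fast=fast)
        except Exception as exc:
            logger.warning("fit of %s failed: %s", ck.value, exc)
    if not results:
        raise RuntimeError("every candidate fit failed")
    rows = []
    for ck, r in results.items():
        value = r.bic if crit == "bic" else r.aic
        rows.append((ck, value, N_PARAMS[ck], r.loglik))
    rows.sort(key=lambda r: (round(r[1] / 1e-6), r[2]))
    best_val = rows[0][1]
    df = pd.DataFrame(
        {
            crit: [r[1] for r in rows],
            "delta": [r[1] - best_val for r in rows],
            "k": [r[2] for r in rows],
            "loglik": [r[3] for r in rows],
        },
        index=pd.Index([r[0].value for r in rows], name="kind"),
    )
    best_kind = rows[0][0]
    if ci_method != "none":
        results[best_kind] = fit_cvm(track, best_kind, likelihood=likelihood,
                                     ci_level=ci_level, ci_method=ci_method)
    df.attrs["results"] = {k.value: v for k, v in results.items()}
    df.attrs["criterion"] = crit
    return df


def subsample_stability(
    track: Track,
    n_grid: Sequence[int],
    reps: int = 1,
    seed: int | None = None,
    *,
    kind: ModelKind | str = ModelKind.UCVM,
    likelihood: str = "kalman",
    ci_method: str = "profile",
) -> pd.DataFrame:
    """Refit a model on random subsamples of increasing size.

    For each n in ``n_grid`` (and each repetition) the track is
    randomly subsampled, refitted, and the estimates of tau and the
    mean speed nu recorded with their confidence intervals — a
    robustness-to-sampling diagnostic.  Failed fits are dropped.
    """
    track = as_track(track)
    if max(n_grid) > len(track):
        raise ValueError("subsample sizes cannot exceed the track length")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        for rep in range(reps):
            sub = track if n == len(track) else subsample_random(track, n, rng)
            try:
                fr = fit_cvm(sub, kind, likelihood=likelihood, ci_method=ci_method)
            except Exception as exc:
                logger.warning("subsample fit (n=%d, rep=%d) failed: %s", n, rep, exc)
                continue
            eta_ci = fr.ci.get("eta", (np.nan, np.nan))
            rows.append(
                {
                    "n": n,
                    "rep": rep,
                    "mean_dt": float(np.mean(np.diff(sub.t))),
                    "tau": fr.params.tau,
                    "tau_lo": fr.ci.get("tau", (np.nan, np.nan))[0],
                    "tau_hi": fr.ci.get("tau", (np.nan, np.nan))[1],
                    "nu": eta_to_nu(fr.params.eta),
                    "nu_lo": eta_to_nu(eta_ci[0]) if np.isfinite(eta_ci[0]) else np.nan,
                    "nu_hi": eta_to_nu(eta_ci[1]) if np.isfinite(eta_ci[1]) else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# correlated-random-walk moment matching
# ---------------------------------------------------------------------


@dataclass
class CRWSummary:
    """Discrete correlated-random-walk summary statistics of a track.

    ``lam`` is the variance/mean ratio of step lengths, ``kappa`` the
    mean cosine of turning angles, ``mean_dt`` the mean sampling
    interval and ``mean_step`` the mean step length.
    """

    lam: float
    kappa: float
    mean_dt: float
    mean_step: float
    n_steps: int
    n_angles_dropped: int = 0


def crw_summary(track: Track) -> CRWSummary:
    """Step-length and turning-angle summaries of a (near-regular) track."""
    track = as_track(track)
    if len(track) < 4:
        raise ValueError("need at least 4 positions for CRW summaries")
    dz = np.diff(track.x) + 1j * np.diff(track.y)
    lengths = np.abs(dz)
    nonzero = lengths > 0
    n_dropped = 0
    angles = np.angle(dz[nonzero])
    if np.sum(~nonzero):
        n_dropped = int(np.sum(~nonzero))
        logger.info("dropped %d zero-length steps from turning angles", n_dropped)
    turns = np.angle(np.exp(1j * np.diff(angles)))
    mean_len = float(np.mean(lengths))
    lam = float(np.var(lengths, ddof=1) / mean_len) if mean_len > 0 else 0.0
    kappa = float(np.mean(np.cos(turns))) if len(turns) else math.nan
    return CRWSummary(
        lam=lam,
        kappa=kappa,
        mean_dt=float(np.mean(np.diff(track.t))),
        mean_step=mean_len,
        n_steps=len(lengths),
        n_angles_dropped=n_dropped,
    )


def _chord_sd(tau: float, dt: float) -> float:
    """Per-component s.d. of a stationary UCVM displacement over dt (eta = 1).

    The innovation variance of the integrated process plus the
    contribution h(dt)^2 Var(v) of the stationary initial velocity,
    h(dt) = tau (1 - e^{-dt/tau}).
    """
    x = dt / tau
    innov = tau * dt + 2.0 * tau * tau * math.expm1(-x) + (tau * tau / 2.0) * (-math.expm1(-2.0 * x))
    h = tau * (-math.expm1(-x))
    return math.sqrt(max(innov + h * h / 2.0, 0.0))


def crw_match(summary: CRWSummary) -> FitResult:
    """Rough UCVM parameters from CRW summary statistics.

    Matches the one-interval velocity autocorrelation, tau = -dt/ln(kappa),
    then recovers eta from the mean step length by inverting the UCVM
    mean-chord formula at that tau (the expected chord of an interval
    dt is sqrt(pi/2) times the per-component displacement s.d., which
    corrects the straight-line-chord underestimate of speed).  The CRW
    is not exactly a sampled UCVM, so this is flagged approximate —
    useful mainly to translate published CRW parameters.
    """
    if not (summary.kappa > 0):
        raise ValueError("CRW matching requires positive turning-angle persistence (kappa > 0)")
    capped = False
    kappa = summary.kappa
    if kappa >= 1.0 - 1e-12:
        kappa = 1.0 - 1e-12
        capped = True
        warnings.warn("kappa ~ 1: tau estimate capped", RuntimeWarning, stacklevel=2)
    tau = -summary.mean_dt / math.log(kappa)
    sd1 = _chord_sd(tau, summary.mean_dt)
    eta = summary.mean_step / (math.sqrt(math.pi / 2.0) * sd1)
    params = CVMParams(kind=ModelKind.UCVM, tau=tau, eta=eta)
    return FitResult(
        params=params,
        ci={},
        loglik=math.nan,
        n_obs=summary.n_steps + 1,
        n_eff=summary.n_steps,
        aic=math.nan,
        bic=math.nan,
        likelihood_method="crw",
        converged=not capped,
        notes="approximate moment-matched estimate; generally biased",
    )
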