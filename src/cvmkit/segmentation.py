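"""Behavioral change-point segmentation of tracks into CVM phases.

A movement phase is a behaviorally homogeneous stretch of track
described by one CVM kind and parameter set.  Segmentation follows a
four-step sweep heuristic:

1. slide a window of fixed size along the track;
2. within each window, find the split (the most likely change point,
   MLCP) maximizing the summed likelihoods of independently fitted
   models on either side;
3. pool the per-window MLCPs and thin them by merging candidates
   closer together than the *cluster width*;
4. test each surviving candidate by comparing the information
   criterion of the two-model description (including one extra
   parameter for the change-point time itself) against the best
   single-model description of the same stretch.

The sweep uses the fast profiled velocity likelihood; candidate
testing and the final per-phase fits use the full position likelihood
with per-side model selection, mirroring a two-resolution workflow
that keeps the whole analysis tractable on tracks of hundreds to
thousands of points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import ALL_KINDS, FitResult, as_track, select_model
from .likelihood import velocities_from_track
from .models import ModelKind, N_PARAMS
from .simulate import Track

__all__ = [
    "SweepConfig",
    "CandidateChangePoint",
    "PhasePartition",
    "sweep_mlcp",
    "thin_candidates",
    "test_candidate",
    "partition",
    "ChangePointSegmenter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """Settings of the change-point sweep.

    ``cluster_width`` is in time units and has no universal default —
    it must be chosen relative to the sampling and the shortest phase
    of interest.  ``window_size``, ``step_size`` and ``min_segment``
    are in observations.
    """

    cluster_width: float
    window_size: int = 50
    step_size: int = 1
    min_segment: int = 10
    candidates: tuple = ALL_KINDS
    criterion: str = "bic"
    likelihood: str = "kalman"

    def __post_init__(self) -> None:
        if self.cluster_width <= 0:
            raise ValueError("cluster_width must be positive (time units)")
        if self.window_size < 2 * self.min_segment:
            raise ValueError("window_size must be at least 2 * min_segment")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if len(self.candidates) == 0:
            raise ValueError("need at least one candidate model kind")


@dataclass
class CandidateChangePoint:
    """A candidate change point elected by the sweep."""

    t_star: float
    support: int = 1
    tested: bool = False
    retained: bool = False
    delta_criterion: float = math.nan

    def __post_init__(self) -> None:
        if self.retained and not self.tested:
            raise ValueError("a retained candidate must have been tested")


@dataclass
class PhasePartition:
    """Ordered, contiguous movement phases covering a track."""

    phases: list[dict]
    change_points: list[CandidateChangePoint]

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def to_frame(self) -> pd.DataFrame:
        """Phase table: model, start/end/duration, parameter estimates."""
        rows = []
        for i, ph in enumerate(self.phases):
            fr: FitResult = ph["fit"]
            p = fr.params
            rows.append(
                {
                    "phase": i + 1,
                    "model": p.kind.value,
                    "start": ph["start"],
                    "end": ph["end"],
                    "duration": ph["end"] - ph["start"],
                    "tau": p.tau,
                    "eta": p.eta,
                    "mu_x": p.mu[0],
                    "mu_y": p.mu[1],
                    "omega": p.omega,
                    "mean_speed": fr.mean_speed,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# fast windowed split scoring (vectorized profiled velocity likelihood)
# ---------------------------------------------------------------------


def _conditional_arrays(v: np.ndarray, t: np.ndarray, tau: float, omega: float):
    """Per-term profile ingredients A=|c|^2/g, B=conj(c) b/g, Q=|b|^2/g, L=ln g."""
    d = np.diff(t)
    a = complex(1.0 / tau, omega)
    G = np.exp(-a * d)
    g = -np.expm1(-2.0 * d / tau) / 2.0
    b = v[1:] - G * v[:-1]
    c = 1.0 - G
    w = 1.0 / g
    return (np.abs(c) ** 2 * w, np.conj(c) * b * w, np.abs(b) ** 2 * w, np.log(g))


def _segment_scores(v, t, tau, omega, advective, splits):
    """Profile log-likelihood of left/right velocity segments at each split.

    ``splits`` are velocity indices k: left = v[0:k], right = v[k:].
    The first velocity of each segment is scored under the stationary
    law; the conditional term crossing the boundary is dropped (phases
    are modeled as independent).  Vectorized over splits with prefix
    sums.
    """
    M = len(v)
    A, B, Q, L = _conditional_arrays(v, t, tau, omega)
    # prefix sums with leading zero: index j holds sum of terms 1..j
    cA = np.concatenate([[0.0], np.cumsum(A)])
    cB = np.concatenate([[0.0j], np.cumsum(B)])
    cQ = np.concatenate([[0.0], np.cumsum(Q)])
    cL = np.concatenate([[0.0], np.cumsum(L)])
    k = np.asarray(splits)

    ln_g0 = math.log(0.5)

    def seg(first_idx, cond_lo, cond_hi, n_terms):
        # stationary term of the segment's first velocity + conditional terms
        v0 = v[first_idx]
        sA = 2.0 + cA[cond_hi] - cA[cond_lo]
        sB = 2.0 * v0 + cB[cond_hi] - cB[cond_lo]
        sQ = 2.0 * np.abs(v0) ** 2 + cQ[cond_hi] - cQ[cond_lo]
        sL = ln_g0 + cL[cond_hi] - cL[cond_lo]
        if advective:
            quad = sQ - np.abs(sB) ** 2 / sA
        else:
            quad = sQ
        quad = np.maximum(quad, 1e-300)
        eta2 = quad / (2.0 * n_terms)
        return -n_terms * (math.log(2.0 * math.pi) + 1.0) - n_terms * np.log(eta2) - sL

    # left: velocities 0..k-1 -> conditional terms 1..k-1
    ll_left = seg(0, 0, k - 1, k.astype(float))
    # right: velocities k..M-1 -> conditional terms k+1..M-1
    ll_right = seg(k, k, M - 1, float(M) - k.astype(float))
    return ll_left, ll_right


def _grids_for(kind: ModelKind, t: np.ndarray, n_tau: int = 14, n_omega: int = 11):
    dts = np.diff(t)
    lo = max(float(np.min(dts)) / 2.0, 1e-9)
    hi = float(t[-1] - t[0]) * 4.0
    taus = np.geomspace(lo, hi, n_tau)
    if kind in (ModelKind.RCVM, ModelKind.RACVM):
        w_max = math.pi / max(float(np.median(dts)), 1e-12)
        half = np.geomspace(w_max / 50.0, w_max, n_omega // 2)
        omegas = np.concatenate([-half[::-1], [0.0], half])
    else:
        omegas = np.array([0.0])
    return taus, omegas


def _window_split_scores(v, t, splits, candidates, criterion="bic"):
    """Criterion-based split score for one window, all splits at once.

    For each side and candidate kind, the profile velocity
    log-likelihood is maximized over a (tau, omega) grid; the side's
    model is chosen by the criterion and the split score is the summed
    two-side score (negative half-criterion).  Returns the score
    vector over splits.
    """
    k = np.asarray(splits)
    nL = k.astype(float)
    nR = float(len(v)) - nL
    pen = np.log if criterion == "bic" else (lambda n: 2.0 * np.ones_like(n))
    best_L = np.full(len(k), -np.inf)
    best_R = np.full(len(k), -np.inf)
    for kind in candidates:
        kind = ModelKind.coerce(kind)
        advective = kind in (ModelKind.ACVM, ModelKind.RACVM)
        taus, omegas = _grids_for(kind, t)
        ll_L = np.full(len(k), -np.inf)
        ll_R = np.full(len(k), -np.inf)
        for tau in taus:
            for om in omegas:
                lL, lR = _segment_scores(v, t, tau, om, advective, k)
                ll_L = np.maximum(ll_L, lL)
                ll_R = np.maximum(ll_R, lR)
        kp = N_PARAMS[kind]
        if criterion == "bic":
            sc_L = ll_L - 0.5 * kp * np.log(np.maximum(nL, 2.0))
            sc_R = ll_R - 0.5 * kp * np.log(np.maximum(nR, 2.0))
        else:
            sc_L = ll_L - kp
            sc_R = ll_R - kp
        best_L = np.maximum(best_L, sc_L)
        best_R = np.maximum(best_R, sc_R)
    return best_L + best_R


def sweep_mlcp(track: Track, config: SweepConfig) -> list[CandidateChangePoint]:
    """Step 1-2 of the heuristic: windowed election of likely change points.

    Every window position (advanced by ``step_size``) elects the
    interior split with at least ``min_segment`` observations per side
    that maximizes the two-sided, per-side-model-selected profiled
    velocity likelihood.  Identical elected times accumulate support.
    """
    track = as_track(track)
    n = len(track)
    W = config.window_size
    if n < W:
        raise ValueError(f"track ({n} obs) shorter than the window ({W})")
    vs = velocities_from_track(track)
    v = vs.v_complex
    tm = vs.t_mid
    support: dict[float, int] = {}
    for p in range(0, n - W + 1, config.step_size):
        # observation split s in [p+min_segment, p+W-min_segment];
        # velocity boundary index (relative to window) k = s - p - 1
        s_lo, s_hi = p + config.min_segment, p + W - config.min_segment
        if s_hi < s_lo:
            continue
        vw = v[p : p + W - 1]
        tw = tm[p : p + W - 1]
        ks = np.arange(s_lo - p - 1, s_hi - p, dtype=int)
        scores = _window_split_scores(vw, tw, ks, config.candidates, config.criterion)
        s_best = s_lo + int(np.argmax(scores))
        t_star = float(track.t[s_best])
        support[t_star] = support.get(t_star, 0) + 1
    return [CandidateChangePoint(t_star=t, support=c) for t, c in sorted(support.items())]


def thin_candidates(cands: list[CandidateChangePoint], cluster_width: float) -> list[CandidateChangePoint]:
    """Step 3: merge candidates closer than ``cluster_width``.

    Greedy left-to-right clustering anchored at each cluster's first
    member; each cluster is replaced by its highest-support member
    (ties broken toward the earlier time) carrying the cluster's
    summed support.
    """
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: c.t_star)
    out: list[CandidateChangePoint] = []
    cluster: list[CandidateChangePoint] = [cands[0]]
    for c in cands[1:]:
        if c.t_star - cluster[0].t_star <= cluster_width:
            cluster.append(c)
        else:
            out.append(_merge_cluster(cluster))
            cluster = [c]
    out.append(_merge_cluster(cluster))
    return out


def _merge_cluster(cluster: list[CandidateChangePoint]) -> CandidateChangePoint:
    best = max(cluster, key=lambda c: (c.support, -c.t_star))
    return CandidateChangePoint(t_star=best.t_star, support=sum(c.support for c in cluster))


def _subtrack(track: Track, i0: int, i1: int) -> Track:
    return Track(t=track.t[i0 : i1 + 1], x=track.x[i0 : i1 + 1], y=track.y[i0 : i1 + 1])


def _best_fit(track: Track, config: SweepConfig) -> FitResult:
    tab = select_model(track, config.candidates, criterion=config.criterion,
                       likelihood=config.likelihood, ci_method="none", fast=True)
    return tab.attrs["results"][tab.index[0]]


def test_candidate(
    track: Track,
    cand: CandidateChangePoint,
    config: SweepConfig,
    *,
    t_lo: float | None = None,
    t_hi: float | None = None,
) -> CandidateChangePoint:
    """Step 4: information-criterion test of one candidate change point.

    Within [t_lo, t_hi] (the whole track by default, or the stretch
    bounded by neighboring candidates during partitioning) the
    two-model description — per-side model selection over the
    candidate kinds, position likelihood, parameter count
    k_left + k_right + 1 with the extra parameter for the change time
    itself — is compared against the best single no-change model.  The
    candidate is retained if the change-point description scores
    lower.  Both descriptions share the boundary observation, so they
    explain the same number of position increments.
    """
    track = as_track(track)
    t = track.t
    lo = t[0] if t_lo is None else t_lo
    hi = t[-1] if t_hi is None else t_hi
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right")) - 1
    s = int(np.searchsorted(t, cand.t_star, side="left"))
    if not (i0 + config.min_segment <= s <= i1 - config.min_segment):
        return replace(cand, tested=False, retained=False)
    sub = _subtrack(track, i0, i1)
    left = _subtrack(track, i0, s)
    right = _subtrack(track, s, i1)
    try:
        fit0 = _best_fit(sub, config)
        fitL = _best_fit(left, config)
        fitR = _best_fit(right, config)
    except Exception as exc:
        logger.warning("candidate at t=%.4g untestable: %s", cand.t_star, exc)
        return replace(cand, tested=False, retained=False)
    n_eff = len(sub) - 1
    k_change = fitL.params.n_params + fitR.params.n_params + 1
    if config.criterion == "bic":
        crit_change = -2.0 * (fitL.loglik + fitR.loglik) + k_change * math.log(n_eff)
        crit_null = -2.0 * fit0.loglik + fit0.params.n_params * math.log(n_eff)
    else:
        crit_change = -2.0 * (fitL.loglik + fitR.loglik) + 2.0 * k_change
        crit_null = -2.0 * fit0.loglik + 2.0 * fit0.params.n_params
    delta = crit_change - crit_null
    return replace(cand, tested=True, retained=bool(delta < 0.0), delta_criterion=float(delta))


def partition(track: Track, config: SweepConfig, *, ci_method: str = "profile") -> PhasePartition:
    """Full change-point analysis: sweep, thin, test, refit phases.

    Candidates surviving the thinning are each tested within the
    stretch bounded by their neighboring candidates; the retained
    change points define contiguous phases (sharing boundary
    observations), each refitted by position likelihood with model
    selection and profile confidence intervals.  A track with no
    retained change point yields a single-phase partition.
    """
    track = as_track(track)
    cands = thin_candidates(sweep_mlcp(track, config), config.cluster_width)
    # Test in decreasing support order, each candidate within the
    # stretch bounded by already-accepted change points; candidates
    # falling within a cluster width of an accepted point are dropped
    # as duplicates of it.
    accepted: list[float] = []
    tested: list[CandidateChangePoint] = []
    for c in sorted(cands, key=lambda c: (-c.support, c.t_star)):
        if any(abs(c.t_star - a) <= config.cluster_width for a in accepted):
            continue
        lo = max([track.t[0]] + [a for a in accepted if a < c.t_star])
        hi = min([track.t[-1]] + [a for a in accepted if a > c.t_star])
        r = test_candidate(track, c, config, t_lo=lo, t_hi=hi)
        tested.append(r)
        if r.retained:
            accepted.append(r.t_star)
    tested.sort(key=lambda c: c.t_star)
    retained = [c for c in tested if c.retained]
    bounds = [float(track.t[0])] + [c.t_star for c in retained] + [float(track.t[-1])]
    phases = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        i0 = int(np.searchsorted(track.t, a, side="left"))
        i1 = int(np.searchsorted(track.t, b, side="right")) - 1
        sub = _subtrack(track, i0, i1)
        tab = select_model(sub, config.candidates, criterion=config.criterion,
                           likelihood=config.likelihood, ci_method=ci_method)
        fr = tab.attrs["results"][tab.index[0]]
        phases.append({"start": a, "end": b, "fit": fr})
    return PhasePartition(phases=phases, change_points=tested)


class ChangePointSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the change-point analysis.

    ``fit`` runs the full sweep/thin/test/refit pipeline;
    ``fit_predict`` additionally returns a per-observation phase label.

    Attributes
    ----------
    partition_ : PhasePartition
    change_points_ : list of retained change-point times
    phase_table_ : pandas.DataFrame summary (one row per phase)
    labels_ : integer phase index per observation
    """

    def __init__(self, cluster_width=1.0, window_size=50, step_size=1, min_segment=10,
                 candidates=ALL_KINDS, criterion="bic", likelihood="kalman"):
        self.cluster_width = cluster_width
        self.window_size = window_size
        self.step_size = step_size
        self.min_segment = min_segment
        self.candidates = candidates
        self.criterion = criterion
        self.likelihood = likelihood

    def _config(self) -> SweepConfig:
        return SweepConfig(
            cluster_width=self.cluster_width,
            window_size=self.window_size,
            step_size=self.step_size,
            min_segment=self.min_segment,
            candidates=tuple(self.candidates),
            criterion=self.criterion,
            likelihood=self.likelihood,
        )

    def fit(self, X, y=None):
        track = as_track(X)
        self.partition_ = partition(track, self._config())
        self.change_points_ = [c.t_star for c in self.partition_.change_points if c.retained]
        self.phase_table_ = self.partition_.to_frame()
        edges = np.array(self.change_points_)
        self.labels_ = np.searchsorted(edges, track.t, side="right")
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
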