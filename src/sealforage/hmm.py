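"""Two-state DCRW hidden Markov model for regularized movement tracks.

The movement process is a first-difference correlated random walk
(DCRW): each planar displacement is a rotated, damped copy of the
previous one plus isotropic Gaussian noise,

    d_t | d_{t-1}, s_t  ~  N( gamma[s] * R(theta[s]) * d_{t-1},
                              sigma[s]^2 * I ),

where the hidden state s_t follows a 2-state Markov chain.  Directed
"travelling" movement has low turning angle and high autocorrelation
(theta ~ 0, gamma > 0.5); tortuous "apparent foraging" movement has
high turning angle and low autocorrelation.  Tracks are first
regularized to a fixed time step (default 3 h) by linear interpolation,
with large gaps splitting a track into segments; the first displacement
of each segment is conditioned on, not modelled.

Fitting is by expectation-maximization with dispersed restarts: since
gamma*R(theta) = [[a, -b], [b, a]] with a = gamma cos theta and
b = gamma sin theta, the weighted complete-data M-step is an exact
linear least-squares update in (a, b), making each iteration closed
form.  Decoding offers both the Viterbi path and forward-backward
posteriors.  State 0 is always the travelling state (larger fitted
gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .tag_io import EARTH_RADIUS_KM

TRAVELLING, FORAGING = 0, 1
STATE_NAMES = {TRAVELLING: "travelling", FORAGING: "foraging"}

_SIGMA_FLOOR = 1e-6
_GAMMA_EPS = 1e-6


def wrap_angle(theta):
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(theta, float), 2 * np.pi)
    return np.where(w > np.pi, w - 2 * np.pi, w)


# ---------------------------------------------------------------------------
# projection and regularization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about (lon0, lat0).

    Distances from the centre are preserved exactly; for foraging-trip
    extents (a few hundred km) the planar distortion is negligible
    relative to movement-process noise.
    """

    lon0: float
    lat0: float
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, float))
        phi0 = np.radians(self.lat0)
        cos_c = np.clip(
            np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam),
            -1.0, 1.0,
        )
        c = np.arccos(cos_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 0, c / np.sin(c), 1.0)
        x = self.radius_km * k * np.cos(phi) * np.sin(lam)
        y = self.radius_km * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, float) / self.radius_km
        y = np.asarray(y, float) / self.radius_km
        rho = np.hypot(x, y)
        c = rho
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_ratio = np.where(rho > 0, np.sin(c) / rho, 1.0)
        phi = np.arcsin(
            np.clip(np.cos(c) * np.sin(phi0) + y * sin_ratio * np.cos(phi0), -1, 1)
        )
        lam = np.arctan2(
            x * np.sin(c),
            rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0),
        )
        lam = np.where(rho > 0, lam, 0.0)
        return self.lon0 + np.degrees(lam), np.degrees(phi)


def project_track(fixes: pd.DataFrame) -> tuple[pd.DataFrame, AzimuthalEquidistant]:
    """Project lon/lat fixes to planar km centred on the track centroid."""
    proj = AzimuthalEquidistant(
        lon0=float(fixes["lon"].mean()), lat0=float(fixes["lat"].mean())
    )
    x, y = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    out = fixes.copy()
    out["x_km"], out["y_km"] = x, y
    return out, proj


def regularize_track(
    fixes: pd.DataFrame,
    step_hours: float = 3.0,
    max_gap_steps: float = 4.0,
) -> pd.DataFrame:
    """Linearly interpolate projected fixes onto a fixed time grid.

    Gaps between consecutive fixes of ``max_gap_steps * step`` or more
    (e.g. haulouts) are never bridged by interpolation: they split the
    track into independently gridded segments, each anchored at its
    first fix.  Bridging a gap as long as the behavioural step would
    manufacture perfectly straight pseudo-steps, which the travelling
    state would absorb with spuriously high autocorrelation.
    Returns columns ``seal_id, segment, timestamp, x_km, y_km``.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to regularize")
    if "x_km" not in fixes:
        fixes, _ = project_track(fixes)
    fixes = fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)
    t = fixes["timestamp"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    step_s = step_hours * 3600.0
    breaks = np.flatnonzero(np.diff(t) >= max_gap_steps * step_s - 1e-6)
    seg_bounds = np.concatenate(([0], breaks + 1, [len(t)]))

    rows = []
    seg_id = 0
    for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
        if e - s < 2:
            continue
        ts, te = t[s], t[e - 1]
        grid = ts + step_s * np.arange(int(np.floor((te - ts) / step_s)) + 1)
        xg = np.interp(grid, t[s:e], fixes["x_km"].to_numpy()[s:e])
        yg = np.interp(grid, t[s:e], fixes["y_km"].to_numpy()[s:e])
        for gt, gx, gy in zip(grid, xg, yg):
            rows.append(
                {
                    "seal_id": fixes["seal_id"].iloc[0] if "seal_id" in fixes else "",
                    "segment": seg_id,
                    "timestamp": pd.Timestamp(gt, unit="s", tz="UTC"),
                    "x_km": gx,
                    "y_km": gy,
                }
            )
        seg_id += 1
    if not rows:
        import warnings

        warnings.warn("all gaps exceed max_gap; empty regular track")
        return pd.DataFrame(columns=["seal_id", "segment", "timestamp", "x_km", "y_km"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass
class HmmParams:
    """State-specific DCRW parameters; index 0 = travelling, 1 = foraging."""

    theta: np.ndarray  # turning angles (rad), wrapped to (-pi, pi]
    gamma: np.ndarray  # autocorrelation in (0, 1)
    sigma: np.ndarray  # process SD (km), > 0
    A: np.ndarray      # 2x2 row-stochastic transition matrix
    delta: np.ndarray  # initial state distribution

    def __post_init__(self):
        self.theta = wrap_angle(np.asarray(self.theta, float))
        self.gamma = np.asarray(self.gamma, float)
        self.sigma = np.asarray(self.sigma, float)
        self.A = np.asarray(self.A, float)
        self.delta = np.asarray(self.delta, float)
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.gamma <= 0) or np.any(self.gamma >= 1):
            raise ValueError("gamma must lie strictly in (0, 1)")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def relabelled(self) -> "HmmParams":
        """Order states so that the larger-gamma state is travelling."""
        if self.gamma[0] >= self.gamma[1]:
            return self
        p = [1, 0]
        return HmmParams(
            theta=self.theta[p], gamma=self.gamma[p], sigma=self.sigma[p],
            A=self.A[np.ix_(p, p)], delta=self.delta[p],
        )


@dataclass
class HmmFit:
    params: HmmParams
    loglik: float
    states: np.ndarray          # Viterbi path over modelled steps
    state_probs: np.ndarray     # forward-backward P(foraging) companion, (T, 2)
    converged: bool
    n_restarts_used: int
    n_iter: int = 0
    step_times: np.ndarray | None = None  # timestamps of modelled steps
    segments: np.ndarray | None = None    # segment id per modelled step


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _segments_to_displacements(track) -> list[np.ndarray]:
    """Per-segment position arrays -> per-segment displacement arrays."""
    if isinstance(track, pd.DataFrame):
        segs = [
            g[["x_km", "y_km"]].to_numpy(float)
            for _, g in track.groupby("segment", sort=True)
        ]
    elif isinstance(track, np.ndarray):
        segs = [np.asarray(track, float)]
    else:
        segs = [np.asarray(s, float) for s in track]
    disps = [np.diff(s, axis=0) for s in segs if len(s) >= 3]
    if not disps:
        raise ValueError("no segment has >= 3 positions")
    for d in disps:
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite positions in track")
    return disps


def _emission_loglik(d: np.ndarray, params: HmmParams) -> np.ndarray:
    """Log N(d_t ; gamma R(theta) d_{t-1}, sigma^2 I) for each state.

    ``d`` holds the segment's displacements (m+1, 2); rows of the result
    (m, 2) correspond to modelled steps t = 1..m.
    """
    prev, cur = d[:-1], d[1:]
    out = np.empty((len(cur), 2))
    for k in range(2):
        a = params.gamma[k] * np.cos(params.theta[k])
        b = params.gamma[k] * np.sin(params.theta[k])
        mx = a * prev[:, 0] - b * prev[:, 1]
        my = b * prev[:, 0] + a * prev[:, 1]
        r2 = (cur[:, 0] - mx) ** 2 + (cur[:, 1] - my) ** 2
        s2 = params.sigma[k] ** 2
        out[:, k] = -np.log(2 * np.pi * s2) - r2 / (2 * s2)
    return out


def _forward(logB: np.ndarray, A: np.ndarray, logdelta: np.ndarray):
    """Log-space forward pass (scaled); returns (log alpha, loglik)."""
    T = len(logB)
    la = np.empty((T, 2))
    la[0] = logdelta + logB[0]
    with np.errstate(divide="ignore"):  # absorbing states give log(0)
        for t in range(1, T):
            m = la[t - 1].max()
            la[t] = logB[t] + m + np.log(np.exp(la[t - 1] - m) @ A)
    return la, float(logsumexp(la[-1]))


def _backward(logB: np.ndarray, A: np.ndarray) -> np.ndarray:
    T = len(logB)
    lb = np.zeros((T, 2))
    with np.errstate(divide="ignore"):
        for t in range(T - 2, -1, -1):
            v = logB[t + 1] + lb[t + 1]
            m = v.max()
            lb[t] = m + np.log(A @ np.exp(v - m))
    return lb


def dcrw_loglik(track, params: HmmParams) -> float:
    """Marginal log-likelihood of the two-state DCRW by the forward
    algorithm, summed over track segments (each re-initialized at
    ``params.delta``)."""
    logdelta = np.log(np.maximum(params.delta, 1e-300))
    total = 0.0
    for d in _segments_to_displacements(track):
        logB = _emission_loglik(d, params)
        _, ll = _forward(logB, params.A, logdelta)
        total += ll
    return total


def decode_states(track, params: HmmParams):
    """Viterbi most-probable state path and forward-backward posteriors.

    Returns ``(states, posteriors)`` concatenated over segments; one
    entry per modelled step (positions 3..n of each segment).
    """
    logA = np.log(np.maximum(params.A, 1e-300))
    logdelta = np.log(np.maximum(params.delta, 1e-300))
    paths, posts = [], []
    for d in _segments_to_displacements(track):
        logB = _emission_loglik(d, params)
        T = len(logB)
        # Viterbi
        dp = np.empty((T, 2))
        bp = np.zeros((T, 2), dtype=int)
        dp[0] = logdelta + logB[0]
        for t in range(1, T):
            cand = dp[t - 1][:, None] + logA
            bp[t] = np.argmax(cand, axis=0)
            dp[t] = logB[t] + np.max(cand, axis=0)
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(dp[-1]))
        for t in range(T - 2, -1, -1):
            path[t] = bp[t + 1][path[t + 1]]
        paths.append(path)
        # forward-backward posteriors
        la, ll = _forward(logB, params.A, logdelta)
        lb = _backward(logB, params.A)
        post = np.exp(la + lb - ll)
        post /= post.sum(axis=1, keepdims=True)
        posts.append(post)
    return np.concatenate(paths), np.vstack(posts)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _em_once(disps, theta0, gamma0, sigma0, A0, delta0,
             max_iter=500, tol=1e-8, sigma_floor=_SIGMA_FLOOR):
    """Run EM from one start; returns (params, loglik, converged, n_iter)."""
    theta, gamma, sigma = theta0.copy(), gamma0.copy(), sigma0.copy()
    A, delta = A0.copy(), delta0.copy()
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        params = HmmParams(theta, gamma, sigma, A, delta)
        logA = np.log(np.maximum(A, 1e-300))
        logdelta = np.log(np.maximum(delta, 1e-300))

        # E-step
        ll = 0.0
        W = []          # per-segment posteriors (T, 2)
        Xi = np.zeros((2, 2))
        first = np.zeros(2)
        for d in disps:
            logB = _emission_loglik(d, params)
            la, seg_ll = _forward(logB, A, logdelta)
            lb = _backward(logB, A)
            ll += seg_ll
            w = np.exp(la + lb - seg_ll)
            w /= w.sum(axis=1, keepdims=True)
            W.append(w)
            first += w[0]
            if len(logB) > 1:
                lx = (
                    la[:-1][:, :, None]
                    + logA[None, :, :]
                    + (logB[1:] + lb[1:])[:, None, :]
                    - seg_ll
                )
                Xi += np.exp(lx).sum(axis=0)

        # M-step: emissions (exact WLS in a = gamma cos th, b = gamma sin th)
        for k in range(2):
            num_a = num_b = den = rss_n = 0.0
            for d, w in zip(disps, W):
                prev, cur = d[:-1], d[1:]
                wk = w[:, k]
                dot = prev[:, 0] * cur[:, 0] + prev[:, 1] * cur[:, 1]
                cross = prev[:, 0] * cur[:, 1] - prev[:, 1] * cur[:, 0]
                num_a += float(np.sum(wk * dot))
                num_b += float(np.sum(wk * cross))
                den += float(np.sum(wk * (prev**2).sum(axis=1)))
                rss_n += float(np.sum(wk))
            a = num_a / max(den, 1e-300)
            b = num_b / max(den, 1e-300)
            g = np.hypot(a, b)
            g_cl = np.clip(g, _GAMMA_EPS, 1.0 - _GAMMA_EPS)
            th = np.arctan2(b, a) if g > 0 else 0.0
            rss = 0.0
            for d, w in zip(disps, W):
                prev, cur = d[:-1], d[1:]
                mx = g_cl * np.cos(th) * prev[:, 0] - g_cl * np.sin(th) * prev[:, 1]
                my = g_cl * np.sin(th) * prev[:, 0] + g_cl * np.cos(th) * prev[:, 1]
                rss += float(
                    np.sum(w[:, k] * ((cur[:, 0] - mx) ** 2 + (cur[:, 1] - my) ** 2))
                )
            gamma[k], theta[k] = g_cl, th
            sigma[k] = max(np.sqrt(rss / max(2 * rss_n, 1e-300)), sigma_floor)

        A = Xi / np.maximum(Xi.sum(axis=1, keepdims=True), 1e-300)
        delta = first / first.sum()
        delta = np.clip(delta, 1e-12, None)
        delta /= delta.sum()

        if ll - ll_old < tol * max(1.0, abs(ll)) and n_iter > 5:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    params = HmmParams(theta, gamma, sigma, A, delta)
    return params, float(ll_old), converged, n_iter


def fit_hmm(
    track,
    n_restarts: int = 10,
    seed: int | None = None,
    min_steps: int = 50,
    max_iter: int = 500,
) -> HmmFit:
    """Fit the two-state DCRW HMM by EM with dispersed restarts.

    Starting points spread the turning angle over {0, pi} and the
    autocorrelation over {0.8, 0.3} (with jitter) to avoid the
    label-switching local optima of the likelihood.  The best restart
    by log-likelihood wins; states are then relabelled so the larger
    fitted gamma is the travelling state.
    """
    disps = _segments_to_displacements(track)
    n_steps = sum(len(d) - 1 for d in disps)
    if n_steps < min_steps:
        raise ValueError(f"only {n_steps} usable displacements (< {min_steps})")
    rng = np.random.default_rng(seed)
    scale = float(np.sqrt(np.mean(np.vstack(disps) ** 2)))

    best = None
    n_used = 0
    for r in range(n_restarts):
        theta0 = np.array([0.0, np.pi]) + rng.normal(0, 0.3, 2)
        gamma0 = np.clip(np.array([0.8, 0.3]) + rng.normal(0, 0.08, 2), 0.05, 0.95)
        sigma0 = scale * np.clip(np.array([1.0, 0.6]) * rng.lognormal(0, 0.2, 2), 0.05, 5)
        stay = rng.uniform(0.75, 0.95, 2)
        A0 = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
        delta0 = np.array([0.5, 0.5])
        try:
            # sigma floored at 1e-3 of the rms displacement: a state may
            # not collapse onto exactly-interpolated track points
            fitres = _em_once(disps, theta0, gamma0, sigma0, A0, delta0,
                              max_iter=max_iter,
                              sigma_floor=max(_SIGMA_FLOOR, 1e-3 * scale))
        except (ValueError, FloatingPointError):
            continue
        n_used += 1
        if best is None or fitres[1] > best[1]:
            best = fitres

    if best is None:
        raise RuntimeError("all restarts failed")
    params, loglik, converged, n_iter = best
    params = params.relabelled()
    states, posts = decode_states(track, params)

    step_times = segments = None
    if isinstance(track, pd.DataFrame):
        parts_t, parts_s = [], []
        for sid, g in track.groupby("segment", sort=True):
            if len(g) >= 3:
                parts_t.append(g["timestamp"].to_numpy()[2:])
                parts_s.append(np.full(len(g) - 2, sid))
        step_times = np.concatenate(parts_t)
        segments = np.concatenate(parts_s)

    return HmmFit(
        params=params, loglik=loglik, states=states, state_probs=posts,
        converged=converged, n_restarts_used=n_used, n_iter=n_iter,
        step_times=step_times, segments=segments,
    )
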