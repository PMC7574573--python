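"""Synthetic tag archives, GPS fixes and GLMM datasets with ground truth.

Every downstream stage of the pipeline is testable without any archival
deployment data: this module generates (a) two-state switching movement
tracks from the same DCRW process the HMM fits, (b) 10-s tag records of
trapezoidal benthic dives with stratified temperature and exponentially
attenuating log-light profiles tied to a chosen chlorophyll field,
(c) Fastloc-style GPS fixes with realistic quality degradation, and
(d) ready-made binary observation tables drawn from the association
GLMMs' own linear predictors.

Defaults emulate a grey-seal foraging-trip deployment on a temperate
continental shelf: 3-h behavioural steps, travelling gamma 0.9 /
foraging gamma 0.2 with turning angles near zero, ~5 dives per hour to
a 40-150 m seafloor, 12-h haulouts every ~5 days, 15-min surface GPS
cadence, and a light sensor spanning 10 decades over 25-225 units
(20 units per decade).  All randomness flows from one integer seed;
a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .enviro import LL_UNITS_PER_DECADE, BioOpticalModel
from .glmm import MODEL1_TERMS, MODEL2_TERMS, ModelSpec, design_matrix
from .hmm import AzimuthalEquidistant

#: deployment site used as the planar origin (lon, lat): Sable Island
ORIGIN_LON, ORIGIN_LAT = -59.9167, 43.95

#: reference fixed-effect sets used by the simulation-recovery studies
#: (units: logit; chl mg m^-3, T50 degC, durations s, depth log-m)
WATER_COLUMN_REFERENCE_COEFS = {
    "intercept": -0.09, "chl": 0.68, "T50": 0.02, "sex": 1.40, "season": 0.32,
    "chl:sex": -0.30, "chl:season": -1.07, "T50:sex": -0.07,
    "T50:season": -0.01, "sex:season": 0.16,
}
BOTTOM_CONDITIONS_REFERENCE_COEFS = {
    "intercept": 0.45, "bot_dur": -0.0013, "bot_temp": 0.02,
    "log_bot_depth": 0.02, "sex": 1.20, "season": -0.10,
    "bot_dur:sex": 0.0005, "bot_dur:season": 0.0, "bot_temp:sex": -0.01,
    "bot_temp:season": 0.0, "log_bot_depth:sex": -0.09,
    "log_bot_depth:season": -0.06, "sex:season": 0.38,
}

#: reference DCRW state parameters (travelling, foraging)
REFERENCE_THETA = (0.0, 0.0)
REFERENCE_GAMMA = (0.9, 0.2)
REFERENCE_SIGMA_KM = (2.5, 1.5)
REFERENCE_TRANSITION = ((0.9, 0.1), (0.05, 0.95))


def _default_seafloor(x, y):
    """Smooth bank-and-basin bathymetry, ~40-150 m."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return 95 + 45 * np.sin(x / 45.0) * np.cos(y / 60.0) - 10 * np.sin(y / 35.0)


def _default_chla(x, y, t_hours):
    """Patchy chlorophyll field, ~0.3-3 mg m^-3."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.exp(
        -0.2 + 0.6 * np.sin(x / 30.0 + 1.0) * np.sin(y / 40.0)
        + 0.3 * np.cos((x + y) / 55.0)
    )


@dataclass(frozen=True)
class TempProfile:
    """Stratified shelf temperature: warm mixed layer over a tanh
    thermocline, with bottom water warming slowly with depth (the
    warm, saline slope-water intrusion typical of shelf basins), so
    bottom temperature varies across banks and basins."""

    surface_c: float = 12.0
    bottom_c: float = 4.0
    thermocline_m: float = 30.0
    thickness_m: float = 8.0
    deep_warming_c_per_m: float = 0.02

    def at(self, depth_m):
        z = np.asarray(depth_m, float)
        frac = 0.5 * (1 - np.tanh((z - self.thermocline_m) / self.thickness_m))
        deep = self.deep_warming_c_per_m * np.maximum(z - self.thermocline_m, 0.0)
        return self.bottom_c + (self.surface_c - self.bottom_c) * frac + deep


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic deployment."""

    n_seals: int = 4
    sex_ratio: float = 0.75          # fraction female (59F:20M ~ 0.75)
    track_steps: int = 400
    step_hours: float = 3.0
    theta: tuple = REFERENCE_THETA
    gamma: tuple = REFERENCE_GAMMA
    sigma_km: tuple = REFERENCE_SIGMA_KM
    transition: tuple = REFERENCE_TRANSITION
    start_time: str = "2014-06-15T00:00:00Z"
    dive_rate_per_hour: float = 5.0
    seafloor_depth_field: Callable = _default_seafloor
    chla_field: Callable = _default_chla
    temp_profile: TempProfile = TempProfile()
    optics: BioOpticalModel = BioOpticalModel()
    surface_ll: float = 220.0
    ll_units_per_decade: float = LL_UNITS_PER_DECADE
    ll_noise_sd: float = 0.5
    #: sensor quantization step for emitted LL (0 = exact values)
    ll_resolution: float = 0.1
    haulout_every_hours: float = 120.0
    haulout_duration_hours: float = 12.0
    gps_interval_min: float = 15.0
    gps_dropout_prob: float = 0.1
    gps_bad_fix_prob: float = 0.02
    gps_jitter_km: float = 0.05
    seed: int = 0

    def __post_init__(self):
        A = np.asarray(self.transition, float)
        if A.shape != (2, 2) or not np.allclose(A.sum(axis=1), 1.0) or (A < 0).any():
            raise ValueError("transition matrix must be 2x2 row-stochastic")
        # gamma = 1 / sigma = 0 admit the deterministic limiting recursion,
        # useful for closed-form checks; fitting still requires the interior
        if not all(0 < g <= 1 for g in self.gamma):
            raise ValueError("gamma must lie in (0, 1]")
        if not all(s >= 0 for s in self.sigma_km):
            raise ValueError("sigma_km must be non-negative")

    def seal_rng(self, seal_id: str, stream: str) -> np.random.Generator:
        """Independent, reproducible stream per (seal, purpose)."""
        key = zlib.crc32(f"{stream}:{seal_id}".encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def simulate_track(
    config: SimConfig,
    seal_id: str = "S1",
    rng: np.random.Generator | None = None,
    initial_displacement: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one two-state DCRW track on the step grid.

    Displacements follow d_t = gamma[s] R(theta[s]) d_{t-1} + eps with
    isotropic Gaussian noise; states follow the Markov chain.  Returns
    (track frame with ``seal_id, timestamp, x_km, y_km``, true states
    per displacement).  The first displacement seeds the recursion, so
    ``positions`` has ``track_steps + 1`` rows and states has
    ``track_steps - 1`` entries aligned with displacements 2..end.
    """
    rng = rng or config.seal_rng(seal_id, "track")
    A = np.asarray(config.transition, float)
    n_disp = config.track_steps
    states = np.empty(n_disp, dtype=int)
    # start from the chain's stationary distribution
    evals, evecs = np.linalg.eig(A.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    pi = np.abs(pi) / np.abs(pi).sum()
    states[0] = rng.choice(2, p=pi)
    for t in range(1, n_disp):
        states[t] = rng.choice(2, p=A[states[t - 1]])

    d = np.empty((n_disp, 2))
    s0 = states[0]
    if initial_displacement is not None:
        d[0] = np.asarray(initial_displacement, float)
    else:
        d[0] = rng.normal(0, config.sigma_km[s0], 2)
    for t in range(1, n_disp):
        k = states[t]
        g, th, sd = config.gamma[k], config.theta[k], config.sigma_km[k]
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d[t] = g * (R @ d[t - 1]) + rng.normal(0, sd, 2)

    pos = np.vstack([[0.0, 0.0], np.cumsum(d, axis=0)])
    t0 = pd.Timestamp(config.start_time)
    times = t0 + pd.to_timedelta(
        np.arange(len(pos)) * config.step_hours, unit="h"
    )
    track = pd.DataFrame(
        {"seal_id": seal_id, "timestamp": times, "x_km": pos[:, 0], "y_km": pos[:, 1]}
    )
    return track, states[1:]  # states for modelled displacements


def haulout_mask(config: SimConfig, times_h: np.ndarray) -> np.ndarray:
    """True where the seal is hauled out, on a regular trip/haulout cycle."""
    cycle = config.haulout_every_hours + config.haulout_duration_hours
    phase = np.mod(times_h, cycle)
    return phase >= config.haulout_every_hours


# ---------------------------------------------------------------------------
# dives and tag records
# ---------------------------------------------------------------------------

def _trapezoid_depths(D, rd, ra, bottom_frac, dt=10.0):
    """10-s depth samples of a trapezoidal dive to depth D."""
    t_desc, t_asc = D / rd, D / ra
    total = (t_desc + t_asc) / (1.0 - bottom_frac)
    t_bot = total - t_desc - t_asc
    t = np.arange(0.0, total + dt, dt)
    depth = np.where(
        t <= t_desc,
        rd * t,
        np.where(t <= t_desc + t_bot, D, np.maximum(D - ra * (t - t_desc - t_bot), 0)),
    )
    return t, depth


def simulate_dive_records(
    config: SimConfig,
    track: pd.DataFrame,
    seal_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the 10-s tag-record stream for one track.

    Benthic trapezoidal dives to the local seafloor, with temperature
    from the stratified profile, LL decaying linearly in depth on the
    log-light scale (slope (units_per_decade/ln 10) * K_d, clamped to
    the 25-225 sensor range), wet at sea and dry during haulouts.
    Returns (records, per-dive truth with true chl-a and K_d).
    """
    rng = rng or config.seal_rng(seal_id, "dives")
    t0 = track["timestamp"].iloc[0]
    rel_h = (
        track["timestamp"] - t0
    ).dt.total_seconds().to_numpy() / 3600.0
    hauled = haulout_mask(config, rel_h)

    rows_t, rows_depth, rows_temp, rows_ll, rows_wet = [], [], [], [], []
    truth_rows = []
    step_s = config.step_hours * 3600.0
    conv = config.ll_units_per_decade / np.log(10.0)

    for i in range(len(track) - 1):
        seg_start = track["timestamp"].iloc[i]
        if hauled[i]:
            # sparse dry samples during the haulout block
            tt = np.arange(0.0, step_s, 300.0)
            rows_t.append(seg_start + pd.to_timedelta(tt, unit="s"))
            rows_depth.append(np.zeros_like(tt))
            rows_temp.append(np.full_like(tt, config.temp_profile.surface_c))
            rows_ll.append(np.full_like(tt, config.surface_ll))
            rows_wet.append(np.zeros_like(tt, dtype=bool))
            continue
        x, y = track["x_km"].iloc[i], track["y_km"].iloc[i]
        seafloor = float(config.seafloor_depth_field(x, y))
        chla = float(config.chla_field(x, y, rel_h[i]))
        K_d = float(config.optics.forward(chla))
        elapsed = 0.0
        while True:
            D = seafloor
            if D <= 0:
                break
            rd, ra = rng.uniform(0.5, 2.5, 2)
            bf = rng.uniform(0.4, 0.6)
            tt, depth = _trapezoid_depths(D, rd, ra, bf)
            if depth.max() > seafloor + 1e-9:
                raise ValueError("dive deeper than seafloor")
            gap = max(30.0, 3600.0 / config.dive_rate_per_hour - tt[-1])
            if elapsed + tt[-1] + gap > step_s:
                break
            temp = config.temp_profile.at(depth)
            ll = config.surface_ll - conv * K_d * depth
            if config.ll_noise_sd > 0:
                ll = ll + rng.normal(0, config.ll_noise_sd, len(ll))
            ll = np.clip(ll, 25.0, 225.0)
            start = seg_start + pd.to_timedelta(elapsed, unit="s")
            rows_t.append(start + pd.to_timedelta(tt, unit="s"))
            rows_depth.append(depth)
            rows_temp.append(temp)
            rows_ll.append(ll)
            rows_wet.append(np.ones_like(tt, dtype=bool))
            # a few surface samples so dives are surface-bounded
            st = tt[-1] + np.array([10.0, gap / 2.0, gap - 10.0])
            rows_t.append(start + pd.to_timedelta(st, unit="s"))
            rows_depth.append(np.zeros(3))
            rows_temp.append(np.full(3, config.temp_profile.at(0.0)))
            surf_ll = np.full(3, config.surface_ll)
            rows_ll.append(np.clip(surf_ll, 25.0, 225.0))
            rows_wet.append(np.ones(3, dtype=bool))
            truth_rows.append(
                {
                    "seal_id": seal_id,
                    "dive_start": start,
                    "true_chla": chla,
                    "true_Kd": K_d,
                    "max_depth_m": float(depth.max()),
                }
            )
            elapsed += tt[-1] + gap

    records = pd.DataFrame(
        {
            "seal_id": seal_id,
            "timestamp": pd.DatetimeIndex(np.concatenate(
                [r.to_numpy() for r in rows_t]
            ), tz="UTC"),
            "depth_m": np.round(np.concatenate(rows_depth), 2),
            "temp_c": np.round(np.concatenate(rows_temp), 3),
            "ll": (
                np.round(np.concatenate(rows_ll) / config.ll_resolution)
                * config.ll_resolution
                if config.ll_resolution > 0
                else np.concatenate(rows_ll)
            ),
            "wet": np.concatenate(rows_wet),
        }
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# GPS
# ---------------------------------------------------------------------------

def simulate_gps_fixes(
    config: SimConfig,
    track: pd.DataFrame,
    seal_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fastloc-style fixes every ~15 min at the surface.

    Fixes linearly interpolate the true path plus ~jitter; each is
    corrupted with probability ``gps_bad_fix_prob`` (few satellites,
    large residual, or an implausible-speed displacement), dropped with
    probability ``gps_dropout_prob``, and suppressed during haulouts
    after the first dry fix.
    """
    rng = rng or config.seal_rng(seal_id, "gps")
    proj = AzimuthalEquidistant(ORIGIN_LON, ORIGIN_LAT)
    t0 = track["timestamp"].iloc[0]
    rel_h = (track["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    total_h = rel_h[-1]
    fix_h = np.arange(0.0, total_h, config.gps_interval_min / 60.0)
    x = np.interp(fix_h, rel_h, track["x_km"].to_numpy())
    y = np.interp(fix_h, rel_h, track["y_km"].to_numpy())
    hauled = haulout_mask(config, fix_h)

    rows = []
    prev_hauled = False
    for i, th in enumerate(fix_h):
        if hauled[i]:
            if prev_hauled:
                continue  # GPS suspended after the first dry fix
            prev_hauled = True
        else:
            prev_hauled = False
        if rng.random() < config.gps_dropout_prob:
            continue
        xi = x[i] + rng.normal(0, config.gps_jitter_km)
        yi = y[i] + rng.normal(0, config.gps_jitter_km)
        nsats = int(rng.integers(5, 11))
        residual = float(np.round(rng.uniform(0, 25), 2))
        if rng.random() < config.gps_bad_fix_prob:
            mode = rng.integers(0, 3)
            if mode == 0:
                nsats = int(rng.integers(2, 5))
            elif mode == 1:
                residual = float(np.round(rng.uniform(31, 120), 2))
            else:
                # displacement implying > 10 m/s over the 15-min gap
                bearing = rng.uniform(0, 2 * np.pi)
                jump = rng.uniform(12, 25) * (config.gps_interval_min * 60) / 1000.0
                xi += jump * np.cos(bearing)
                yi += jump * np.sin(bearing)
        lon, lat = proj.inverse(xi, yi)
        rows.append(
            {
                "seal_id": seal_id,
                "timestamp": t0 + pd.Timedelta(hours=th),
                "lon": float(np.round(lon, 6)),
                "lat": float(np.round(lat, 6)),
                "nsats": nsats,
                "residual": residual,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLMM datasets
# ---------------------------------------------------------------------------

def simulate_glmm_dataset(
    coefs: dict[str, float],
    n_seals: int = 40,
    n_obs_per_seal: int = 200,
    re_sd: float = 0.5,
    rho_step: float = 0.5,
    step_hours: float = 3.0,
    seed: int = 0,
    model: str = "model1",
    eps_sd: float = 0.5,
    female_fraction: float = 0.5,
    gap_prob: float = 0.05,
    gap_hours: float = 12.0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a binary observation table from a model's linear predictor.

    ``coefs`` maps term names (see :data:`sealforage.glmm.MODEL1_TERMS`
    / ``MODEL2_TERMS`` plus ``intercept``) to generative values.  Each
    seal gets a Gaussian intercept (SD ``re_sd``) and a latent CAR(1)
    Gaussian residual (SD ``eps_sd``; correlation ``rho_step`` between
    observations one step apart, decaying as rho_step**(lag/step) over
    the haulout gaps inserted with probability ``gap_prob``).  Seasons
    split the deployment in half (summer then fall).  Returns the table
    and a ground-truth bundle (coefs, per-seal intercepts).
    """
    if not 0 <= rho_step < 1:
        raise ValueError("rho_step must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    terms = MODEL1_TERMS if model == "model1" else MODEL2_TERMS
    missing = set(coefs) - set(terms) - {"intercept"}
    if missing:
        raise ValueError(f"unknown terms in coefs: {sorted(missing)}")
    beta = np.array([coefs.get("intercept", 0.0)] + [coefs.get(t, 0.0) for t in terms])
    rho_h = rho_step ** (1.0 / step_hours) if rho_step > 0 else 0.0

    frames = []
    nu = rng.normal(0.0, re_sd, n_seals) if re_sd > 0 else np.zeros(n_seals)
    n_female = int(round(female_fraction * n_seals))
    sexes = np.array(["F"] * n_female + ["M"] * (n_seals - n_female))
    for i in range(n_seals):
        gaps = np.where(rng.random(n_obs_per_seal) < gap_prob, gap_hours, 0.0)
        gaps[0] = 0.0
        t = np.cumsum(np.full(n_obs_per_seal, step_hours) + gaps) - step_hours
        season = np.where(np.arange(n_obs_per_seal) < n_obs_per_seal // 2,
                          "summer", "fall")
        d = {
            "seal_id": f"S{i:03d}",
            "t_hours": t,
            "sex": sexes[i],
            "season": season,
        }
        if model == "model1":
            d["chl"] = rng.lognormal(np.log(0.8), 0.5, n_obs_per_seal)
            d["T50"] = rng.normal(8.0, 2.5, n_obs_per_seal)
        else:
            d["bot_dur"] = np.clip(rng.normal(180.0, 60.0, n_obs_per_seal), 20, 600)
            d["bot_temp"] = rng.normal(5.0, 2.5, n_obs_per_seal)
            d["log_bot_depth"] = rng.normal(4.0, 0.6, n_obs_per_seal)
        df = pd.DataFrame(d)
        # latent CAR(1) noise over the (gappy) time grid
        if eps_sd > 0:
            eps = np.empty(n_obs_per_seal)
            eps[0] = rng.normal(0, eps_sd)
            if rho_h > 0:
                r = rho_h ** np.diff(t)
                innov_sd = eps_sd * np.sqrt(1 - r**2)
                white = rng.normal(0, 1, n_obs_per_seal - 1)
                for j in range(1, n_obs_per_seal):
                    eps[j] = r[j - 1] * eps[j - 1] + innov_sd[j - 1] * white[j - 1]
            else:
                eps[1:] = rng.normal(0, eps_sd, n_obs_per_seal - 1)
        else:
            eps = np.zeros(n_obs_per_seal)
        spec = ModelSpec(name=model, terms=list(terms))
        X, _ = design_matrix(df, spec)
        eta = X @ beta + nu[i] + eps
        df["y"] = (rng.random(n_obs_per_seal) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        frames.append(df)
    obs = pd.concat(frames, ignore_index=True)
    truth = {
        "coefs": dict(coefs), "re_sd": re_sd, "rho_step": rho_step,
        "eps_sd": eps_sd,
        "seal_effects": {f"S{i:03d}": nu[i] for i in range(n_seals)},
        "nu": nu, "terms": ["intercept"] + list(terms),
    }
    return obs, truth


# ---------------------------------------------------------------------------
# whole-deployment convenience
# ---------------------------------------------------------------------------

def simulate_deployment(config: SimConfig) -> dict:
    """Simulate tracks, tag records, GPS fixes and truth for all seals.

    Returns a dict with per-seal frames concatenated: ``tracks``,
    ``states`` (true behavioural states), ``records``, ``gps``,
    ``dive_truth`` and the seal ``metadata`` (sex map).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_female = int(round(config.sex_ratio * config.n_seals))
    tracks, states, records, gps, truth = [], [], [], [], []
    metadata = {}
    for i in range(config.n_seals):
        sid = f"S{i:03d}"
        metadata[sid] = "F" if i < n_female else "M"
        tr, st = simulate_track(config, sid)
        rec, tru = simulate_dive_records(config, tr, sid)
        fx = simulate_gps_fixes(config, tr, sid)
        tracks.append(tr)
        states.append(
            pd.DataFrame(
                {
                    "seal_id": sid,
                    "timestamp": tr["timestamp"].iloc[2:].to_numpy(),
                    "state": st,
                }
            )
        )
        records.append(rec)
        gps.append(fx)
        truth.append(tru)
    return {
        "tracks": pd.concat(tracks, ignore_index=True),
        "states": pd.concat(states, ignore_index=True),
        "records": pd.concat(records, ignore_index=True),
        "gps": pd.concat(gps, ignore_index=True),
        "dive_truth": pd.concat(truth, ignore_index=True),
        "metadata": metadata,
    }
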