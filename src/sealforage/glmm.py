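"""Binomial GLMMs linking behavioural state to oceanographic covariates.

Two models associate the probability of the apparent-foraging state with
in-situ covariates, on the logit scale with all two-way interactions:

- Water Column Model ("model1"): chlorophyll-a, T50, sex, season;
- Bottom Conditions Model ("model2"): bottom duration, bottom
  temperature, log bottom depth, sex, season.

Both include a Gaussian per-seal random intercept and a continuous-time
first-order autoregressive (CAR(1)) residual correlation
corr(t_i, t_j) = rho**|t_i - t_j| (time in hours), which accommodates
the irregular gaps left by haulouts and the noon-window chlorophyll
restriction.  Estimation is by penalized quasi-likelihood (PQL): the
binary response is linearized to a working response

    z = eta + (y - mu) / (mu (1 - mu)),   weights w = mu (1 - mu),

and a weighted linear mixed model with random intercept + CAR(1)
residual is fitted to z by REML; the linear predictor is updated from
the fixed estimates and intercept BLUPs, and the two steps alternate to
convergence.

The CAR(1) correlation over ordered times is a Markov (product)
correlation, so its inverse is tridiagonal with a closed form: for lag
correlations r_k = rho**dt_k, the Gaussian innovations give

    v' C^-1 v = v_1^2 + sum_k (v_{k+1} - r_k v_k)^2 / (1 - r_k^2),
    log det C = sum_k log(1 - r_k^2).

Combined with a rank-one Woodbury update for the random intercept, each
REML objective evaluation is O(N), which keeps simulation studies with
thousands of observations per fit cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import t as t_dist

# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

#: columns a term name may refer to; sex/season are indicator-coded with
#: male and fall as the reference levels (the intercept is males in fall)
_BASE_VARS = {
    "sex": lambda df: (df["sex"].astype(str) == "F").astype(float).to_numpy(),
    "season": lambda df: (df["season"].astype(str) == "summer").astype(float).to_numpy(),
}

MODEL1_TERMS = [
    "chl", "T50", "sex", "season",
    "chl:sex", "chl:season", "T50:sex", "T50:season", "sex:season",
]
MODEL2_TERMS = [
    "bot_dur", "bot_temp", "log_bot_depth", "sex", "season",
    "bot_dur:sex", "bot_dur:season", "bot_temp:sex", "bot_temp:season",
    "log_bot_depth:sex", "log_bot_depth:season", "sex:season",
]


@dataclass
class ModelSpec:
    """Fixed-effect terms plus variance-component options.

    ``rho`` / ``re_sd`` of ``None`` mean "estimate by REML"; a number
    fixes the component (0 turns it off, recovering ordinary logistic
    regression when both are 0).  ``rho`` is the CAR(1) correlation per
    hour.
    """

    name: str
    terms: list[str]
    response: str = "y"
    group: str = "seal_id"
    time: str = "t_hours"
    rho: float | None = None
    re_sd: float | None = None
    max_iter: int = 50
    tol: float = 1e-6


def water_column_model(**kw) -> ModelSpec:
    return ModelSpec(name="water_column", terms=list(MODEL1_TERMS), **kw)


def bottom_conditions_model(**kw) -> ModelSpec:
    return ModelSpec(name="bottom_conditions", terms=list(MODEL2_TERMS), **kw)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    cols = []
    for part in term.split(":"):
        if part in _BASE_VARS:
            cols.append(_BASE_VARS[part](df))
        else:
            cols.append(df[part].to_numpy(float))
    out = cols[0].copy()
    for c in cols[1:]:
        out = out * c
    return out


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix for the spec's terms."""
    names = ["intercept"] + list(spec.terms)
    X = np.column_stack(
        [np.ones(len(df))] + [_term_column(df, t) for t in spec.terms]
    )
    return X, names


def model_frame(obs: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    """Rows usable by the model: listwise-drop missing required covariates.

    Returns the retained frame (sorted by seal then time) and the number
    of dropped rows.
    """
    needed = {p for t in spec.terms for p in t.split(":")} - set(_BASE_VARS)
    sub = obs.dropna(subset=sorted(needed) + [spec.response])
    n_dropped = len(obs) - len(sub)
    sub = sub.sort_values([spec.group, spec.time], kind="stable").reset_index(drop=True)
    return sub, n_dropped


# ---------------------------------------------------------------------------
# CAR(1) machinery
# ---------------------------------------------------------------------------

def car1_corr(times, rho: float) -> np.ndarray:
    """Dense CAR(1) correlation matrix rho**|t_i - t_j| (times in hours)."""
    if not abs(rho) < 1:
        raise ValueError("CAR(1) requires |rho| < 1")
    t = np.asarray(times, float)
    lag = np.abs(t[:, None] - t[None, :])
    if rho == 0:
        return np.eye(len(t))
    if rho > 0:
        return rho**lag
    # negative rho only has a real-valued power on an integer lag grid
    if not np.allclose(lag, np.round(lag), atol=1e-9):
        raise ValueError("negative rho requires integer time lags")
    ilag = np.round(lag).astype(int)
    return np.where(ilag % 2 == 0, 1.0, -1.0) * np.abs(rho) ** lag


class _Car1Blocks:
    """O(N) operations with V~ = W^-1/2 C W^-1/2 + lambda 1 1' (block
    diagonal by seal, times sorted within seal)."""

    def __init__(self, t_hours: np.ndarray, seal_codes: np.ndarray, w: np.ndarray):
        self.n = len(t_hours)
        self.starts = np.flatnonzero(
            np.concatenate(([True], seal_codes[1:] != seal_codes[:-1]))
        )
        self.is_start = np.zeros(self.n, dtype=bool)
        self.is_start[self.starts] = True
        self.is_end = np.roll(self.is_start, -1)
        dt = np.empty(self.n)
        dt[0] = 0.0
        dt[1:] = t_hours[1:] - t_hours[:-1]
        dt[self.is_start] = 0.0
        if np.any(dt < 0):
            raise ValueError("times must be sorted within seal")
        self.dt = dt
        self.sqw = np.sqrt(w)

    def set_rho(self, rho: float) -> None:
        r = np.zeros(self.n)
        nz = ~self.is_start
        r[nz] = np.sign(rho) * np.abs(rho) ** self.dt[nz] if rho != 0 else 0.0
        self.r = r
        self.D = 1.0 - r**2  # innovation variances; 1 at seal starts

    def rinv(self, V: np.ndarray) -> np.ndarray:
        """R~^-1 V with R~ = W^-1/2 C W^-1/2, columns of V independent."""
        V = self.sqw[:, None] * V
        Lv = V.copy()
        Lv[1:] -= self.r[1:, None] * V[:-1]
        Lv[self.is_start] = V[self.is_start]
        u = Lv / self.D[:, None]
        out = u.copy()
        out[:-1] -= self.r[1:, None] * u[1:]
        return self.sqw[:, None] * out

    def logdet_rtilde(self, w: np.ndarray) -> float:
        return float(np.sum(np.log(self.D)) - np.sum(np.log(w)))

    def per_seal_sums(self, V: np.ndarray) -> np.ndarray:
        return np.add.reduceat(V, self.starts, axis=0)


def _reml_objective(blocks: _Car1Blocks, X, z, w, rho, lam):
    """Profiled -2 REML log-likelihood and the GLS by-products."""
    blocks.set_rho(rho)
    N, p = X.shape
    U = np.column_stack([X, z, np.ones(N)])
    P = blocks.rinv(U)
    PX, Pz, P1 = P[:, :p], P[:, p], P[:, p + 1]
    s = blocks.per_seal_sums(P1[:, None]).ravel()          # 1' R~^-1 1 per seal
    H = blocks.per_seal_sums(P[:, : p + 1])                # [X z]' R~^-1 1
    G = U[:, : p + 1].T @ P[:, : p + 1]                    # [X z]' R~^-1 [X z]
    c = lam / (1.0 + lam * s)                               # Woodbury factors
    M = G - (H * c[:, None]).T @ H
    Mxx, Mxz, Mzz = M[:p, :p], M[:p, p], M[p, p]
    if not np.all(np.isfinite(M)):
        return np.inf, None
    try:
        beta = np.linalg.solve(Mxx, Mxz)
    except np.linalg.LinAlgError:
        return np.inf, None
    Q = float(Mzz - beta @ Mxz)
    if Q <= 0:
        return np.inf, None
    sigma2 = Q / (N - p)
    sign, logdet_Mxx = np.linalg.slogdet(Mxx)
    if sign <= 0:
        return np.inf, None
    logdet_V = blocks.logdet_rtilde(w) + float(np.sum(np.log1p(lam * s)))
    neg2 = (N - p) * (np.log(sigma2) + 1.0) + logdet_V + logdet_Mxx
    # per-seal BLUP pieces: u_i = 1' R~^-1 (z - X beta)
    u = blocks.per_seal_sums((Pz - PX @ beta)[:, None]).ravel()
    blup = lam * u / (1.0 + lam * s)
    return neg2, {
        "beta": beta, "sigma2": sigma2, "cov_unscaled": np.linalg.inv(Mxx),
        "blup": blup, "s": s,
    }


def _fit_lmm(blocks, X, z, w, rho_fixed, lam_fixed, x0):
    """REML over free components among (rho, lambda); returns fit dict."""

    def unpack(v):
        i = 0
        if rho_fixed is None:
            # per-hour correlation capped below 1 so innovation variances
            # 1 - rho^(2 dt) stay numerically positive
            rho = float(np.clip(expit(v[i]), 0.0, 0.995)); i += 1
        else:
            rho = rho_fixed
        lam = float(np.exp(np.clip(v[i], -30, 15))) if lam_fixed is None else lam_fixed
        return rho, lam

    free = (rho_fixed is None) + (lam_fixed is None)
    if free == 0:
        rho, lam = rho_fixed, lam_fixed
        neg2, aux = _reml_objective(blocks, X, z, w, rho, lam)
        x_opt = np.empty(0)
    else:
        def obj(v):
            rho, lam = unpack(v)
            val, _ = _reml_objective(blocks, X, z, w, rho, lam)
            return val if np.isfinite(val) else 1e15

        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400})
        x_opt = res.x
        rho, lam = unpack(res.x)
        neg2, aux = _reml_objective(blocks, X, z, w, rho, lam)
    if aux is None:
        raise RuntimeError("REML objective degenerate at optimum")
    aux.update(rho=rho, lam=lam, neg2=neg2, x_opt=x_opt)
    return aux


# ---------------------------------------------------------------------------
# PQL outer loop
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    """PQL fit: coefficients, variance components and the Wald table."""

    spec: ModelSpec
    terms: list[str]
    coefs: np.ndarray
    se: np.ndarray
    rho: float
    re_sd: float
    resid_scale: float              # quasi-dispersion sigma^2
    t_stats: np.ndarray = field(default=None)
    df: np.ndarray = field(default=None)
    p_values: np.ndarray = field(default=None)
    converged: bool = False
    n_iter: int = 0
    n_obs: int = 0
    n_seals: int = 0
    n_dropped: int = 0
    ranef: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms, "coef": self.coefs, "se": self.se,
                "t": self.t_stats, "df": self.df, "p": self.p_values,
            }
        )


def _wald_df(X: np.ndarray, seal_codes: np.ndarray, n_seals: int) -> np.ndarray:
    """Containment df: columns constant within every seal are tested
    against between-seal df, the rest against within-seal df."""
    N, p = X.shape
    between = np.ones(p, dtype=bool)
    order = np.argsort(seal_codes, kind="stable")
    for j in range(p):
        col = X[order, j]
        grp = seal_codes[order]
        # varies within some seal?
        same_seal = grp[1:] == grp[:-1]
        if np.any(same_seal & (np.abs(np.diff(col)) > 1e-12)):
            between[j] = False
    n_between = int(between.sum())
    n_within = p - n_between
    df = np.where(between, max(n_seals - n_between, 1),
                  max(N - n_seals - n_within, 1))
    return df.astype(float)


def fit_pql_glmm(obs: pd.DataFrame, spec: ModelSpec) -> GlmmFit:
    """Fit a binomial logit GLMM by penalized quasi-likelihood.

    ``obs`` needs the spec's response (0/1), group, time (hours) and
    covariate columns; rows missing a required covariate are dropped
    listwise.  Requires at least 2 seals, and both sexes present when
    sex enters the model.
    """
    df, n_dropped = model_frame(obs, spec)
    seals = df[spec.group].astype(str)
    n_seals = seals.nunique()
    if n_seals < 2:
        raise ValueError("need >= 2 seals")
    if any("sex" in t for t in spec.terms) and df["sex"].nunique() < 2:
        raise ValueError("sex in model but only one sex present")

    X, names = design_matrix(df, spec)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]} columns; a factor "
            "is constant (e.g. single-season data) or terms are collinear"
        )
    y = df[spec.response].to_numpy(float)
    t_hours = df[spec.time].to_numpy(float)
    seal_codes = pd.factorize(seals)[0]
    N, p = X.shape

    rho_fixed = spec.rho
    lam_fixed = None
    if spec.re_sd is not None and spec.re_sd == 0:
        lam_fixed = 0.0
    # (a nonzero fixed re_sd still requires lambda = re_sd^2/sigma^2 to
    #  track sigma^2, so only the off switch is supported as fixed)

    mu = (y + 0.5) / 2.0
    eta = logit(mu)
    beta = np.zeros(p)
    converged = False
    x0 = np.array(
        ([logit(0.5)] if rho_fixed is None else []) + ([np.log(0.1)] if lam_fixed is None else [])
    )
    fit = None
    for it in range(1, spec.max_iter + 1):
        mu = np.clip(expit(eta), 1e-6, 1 - 1e-6)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        blocks = _Car1Blocks(t_hours, seal_codes, w)
        fit = _fit_lmm(blocks, X, z, w, rho_fixed, lam_fixed, x0)
        if fit["x_opt"].size:
            x0 = fit["x_opt"]  # warm start the variance search
        beta_new = fit["beta"]
        eta = X @ beta_new + fit["blup"][seal_codes]
        delta = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta = beta_new
        if delta < spec.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PQL did not converge in {spec.max_iter} iterations")
    if np.any(np.abs(beta) > 15):
        warnings.warn("possible separation: |coefficient| > 15")

    sigma2 = fit["sigma2"]
    se = np.sqrt(sigma2 * np.diag(fit["cov_unscaled"]))
    dfree = _wald_df(X, seal_codes, n_seals)
    tstat = beta / se
    pvals = 2 * t_dist.sf(np.abs(tstat), dfree)
    ranef = pd.Series(
        fit["blup"], index=pd.unique(seals), name="intercept_blup"
    )
    return GlmmFit(
        spec=spec, terms=names, coefs=beta, se=se,
        rho=float(fit["rho"]), re_sd=float(np.sqrt(fit["lam"] * sigma2)),
        resid_scale=float(sigma2), t_stats=tstat, df=dfree, p_values=pvals,
        converged=converged, n_iter=it, n_obs=N, n_seals=n_seals,
        n_dropped=n_dropped, ranef=ranef,
    )


def odds_ratio_table(fit: GlmmFit) -> pd.DataFrame:
    """Exponentiated coefficients with Wald 95% CIs and p-values."""
    lo = np.exp(fit.coefs - 1.96 * fit.se)
    hi = np.exp(fit.coefs + 1.96 * fit.se)
    return pd.DataFrame(
        {
            "term": fit.terms,
            "coef": fit.coefs,
            "se": fit.se,
            "or": np.exp(fit.coefs),
            "ci_lo": lo,
            "ci_hi": hi,
            "p": fit.p_values,
        }
    )


# ---------------------------------------------------------------------------
# observation assembly
# ---------------------------------------------------------------------------

def season_of(ts: pd.Timestamp) -> str | None:
    """summer = Jun-Aug, fall = Sep-Dec; other months unusable (the
    breeding-season return empties January, and deployments span
    Jun-Dec)."""
    m = pd.Timestamp(ts).month
    if 6 <= m <= 8:
        return "summer"
    if 9 <= m <= 12:
        return "fall"
    return None


def assemble_observations(
    states: pd.DataFrame,
    env: pd.DataFrame,
    metadata: dict[str, str],
    step_hours: float = 3.0,
) -> pd.DataFrame:
    """Join decoded states with per-dive covariate medians.

    For each decoded step at time t, covariates are medians over that
    seal's dives ending in the window (t - step, t].  ``states`` needs
    columns ``seal_id, timestamp, state`` (1 = apparent foraging);
    ``env`` is the :func:`sealforage.enviro.enviro_table` output;
    ``metadata`` maps seal_id -> sex ('F'/'M').  Steps in months outside
    June-December are dropped; missing covariates are left NaN for
    per-model listwise dropping.  Bottom depth is log-transformed.
    """
    rows = []
    env = env.copy()
    env["dive_end"] = pd.to_datetime(env["dive_end"], utc=True)
    for seal_id, grp in states.groupby("seal_id", sort=True):
        sid = str(seal_id)
        if sid not in metadata:
            raise ValueError(f"seal {sid} missing from metadata (sex unknown)")
        sex = metadata[sid]
        if sex not in ("F", "M"):
            raise ValueError(f"seal {sid}: unknown sex {sex!r}")
        e = env[env["seal_id"].astype(str) == sid]
        ends = e["dive_end"]
        for _, row in grp.iterrows():
            t = pd.Timestamp(row["timestamp"])
            season = season_of(t)
            if season is None:
                continue
            lo = t - pd.Timedelta(hours=step_hours)
            sel = e.loc[(ends > lo) & (ends <= t)]

            def med(col):
                v = sel[col].dropna()
                return float(v.median()) if len(v) else np.nan

            bot_depth = med("bot_depth_m")
            rows.append(
                {
                    "seal_id": sid,
                    "timestamp": t,
                    "t_hours": t.timestamp() / 3600.0,
                    "y": int(row["state"]),
                    "sex": sex,
                    "season": season,
                    "chl": med("chla_mg_m3"),
                    "T50": med("T50"),
                    "bot_dur": med("bot_dur_s"),
                    "bot_temp": med("bot_temp_c"),
                    "log_bot_depth": (
                        np.log(bot_depth) if bot_depth > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
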