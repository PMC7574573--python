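"""CAR(1) structure, PQL estimation and the observation assembly rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sealforage import glmm
from sealforage import synthetic as syn


class TestCar1:
    def test_zero_rho_identity(self):
        C = glmm.car1_corr([0.0, 3.0, 7.5], 0.0)
        assert np.array_equal(C, np.eye(3))

    def test_three_hour_grid_entries(self):
        C = glmm.car1_corr([0.0, 3.0, 6.0], 0.8)
        assert C[0, 1] == pytest.approx(0.8**3)
        assert C[0, 2] == pytest.approx(0.8**6)
        assert C[0, 2] == pytest.approx(0.262144)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_positive_definite_random_time_sets(self):
        """Cholesky succeeds across rho in (-0.99, 0.99) and random
        irregular time sets (integer grids for negative rho)."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            rho = rng.uniform(-0.99, 0.99)
            n = int(rng.integers(3, 40))
            if rho < 0:
                times = np.sort(rng.choice(200, size=n, replace=False)).astype(float)
            else:
                times = np.sort(rng.uniform(0, 500, n))
            C = glmm.car1_corr(times, rho)
            np.linalg.cholesky(C + 1e-12 * np.eye(n))

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            glmm.car1_corr([0.0, 1.0], 1.0)

    def test_tridiagonal_solver_matches_dense_inverse(self):
        """The O(N) innovation solver agrees with the dense inverse."""
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 50, 25))
        w = rng.uniform(0.5, 2.0, 25)
        rho = 0.7
        blocks = glmm._Car1Blocks(t, np.zeros(25, dtype=int), w)
        blocks.set_rho(rho)
        V = rng.normal(0, 1, (25, 3))
        fast = blocks.rinv(V)
        C = glmm.car1_corr(t, rho)
        R = np.diag(1 / np.sqrt(w)) @ C @ np.diag(1 / np.sqrt(w))
        dense = np.linalg.solve(R, V)
        assert np.allclose(fast, dense, atol=1e-9)
        ld = blocks.logdet_rtilde(w)
        assert ld == pytest.approx(np.linalg.slogdet(R)[1], abs=1e-9)


class TestPql:
    def test_degenerate_matches_ordinary_logistic(self):
        """rho = 0 and re_sd = 0 reduces PQL to IRLS: coefficients agree
        with a plain logistic GLM to 1e-4."""
        obs, _ = syn.simulate_glmm_dataset(
            syn.WATER_COLUMN_REFERENCE_COEFS, n_seals=10, n_obs_per_seal=150,
            re_sd=0.0, rho_step=0.0, eps_sd=0.0, seed=5)
        spec = glmm.water_column_model(rho=0.0, re_sd=0.0)
        fit = glmm.fit_pql_glmm(obs, spec)
        frame, _ = glmm.model_frame(obs, spec)
        X, _ = glmm.design_matrix(frame, spec)
        oracle = sm.GLM(frame["y"].to_numpy(), X,
                        family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coefs - oracle.params)) < 1e-4

    def test_null_simulation_calibration(self):
        """Under an all-zero generative model, estimated coefficients stay
        within 2 SE of zero in the vast majority of cases."""
        hits, total = 0, 0
        for s in range(12):
            obs, _ = syn.simulate_glmm_dataset(
                {}, n_seals=20, n_obs_per_seal=100, re_sd=0.0,
                rho_step=0.0, eps_sd=0.0, seed=400 + s)
            fit = glmm.fit_pql_glmm(obs, glmm.water_column_model(rho=0.0, re_sd=0.0))
            hits += int(np.sum(np.abs(fit.coefs) < 2 * fit.se))
            total += len(fit.coefs)
        assert hits / total >= 0.85

    def test_variance_components_recovered(self):
        """With a strong random effect the REML step attributes the
        between-seal spread to the intercept SD."""
        obs, _ = syn.simulate_glmm_dataset(
            {"intercept": 0.5}, n_seals=60, n_obs_per_seal=100,
            re_sd=1.0, rho_step=0.0, eps_sd=0.0, seed=6)
        fit = glmm.fit_pql_glmm(obs, glmm.ModelSpec(name="null", terms=["sex"]))
        assert 0.6 < fit.re_sd < 1.4

    def test_requires_two_seals(self):
        obs, _ = syn.simulate_glmm_dataset({}, n_seals=1, n_obs_per_seal=30,
                                           seed=0)
        with pytest.raises(ValueError, match="2 seals"):
            glmm.fit_pql_glmm(obs, glmm.water_column_model())


class TestOddsRatios:
    def _fit(self, coefs, ses):
        spec = glmm.ModelSpec(name="x", terms=[])
        return glmm.GlmmFit(
            spec=spec, terms=[f"b{i}" for i in range(len(coefs))],
            coefs=np.asarray(coefs, float), se=np.asarray(ses, float),
            rho=0.0, re_sd=0.0, resid_scale=1.0,
            t_stats=np.zeros(len(coefs)), df=np.ones(len(coefs)),
            p_values=np.ones(len(coefs)),
        )

    def test_zero_coefficient_gives_unit_or(self):
        tab = glmm.odds_ratio_table(self._fit([0.0], [0.5]))
        assert tab["or"].iloc[0] == 1.0
        assert tab["ci_lo"].iloc[0] < 1.0 < tab["ci_hi"].iloc[0]

    def test_closed_form_interval(self):
        """beta 1.40, SE 0.36 exponentiates to OR 4.06 [2.00, 8.22]."""
        tab = glmm.odds_ratio_table(self._fit([1.40], [0.36]))
        assert tab["or"].iloc[0] == pytest.approx(np.exp(1.40), rel=1e-12)
        assert tab["or"].iloc[0] == pytest.approx(4.06, abs=0.01)
        assert tab["ci_lo"].iloc[0] == pytest.approx(np.exp(1.40 - 1.96 * 0.36), rel=1e-12)
        assert tab["ci_lo"].iloc[0] == pytest.approx(2.00, abs=0.01)
        assert tab["ci_hi"].iloc[0] == pytest.approx(8.22, abs=0.01)

    def test_zero_se_degenerate_interval(self):
        tab = glmm.odds_ratio_table(self._fit([0.7], [0.0]))
        assert tab["ci_lo"].iloc[0] == tab["or"].iloc[0] == tab["ci_hi"].iloc[0]

    def test_table_is_elementwise_exponential(self):
        rng = np.random.default_rng(11)
        coefs = rng.normal(0, 1, 6)
        ses = rng.uniform(0.1, 1, 6)
        tab = glmm.odds_ratio_table(self._fit(coefs, ses))
        assert np.allclose(tab["or"], np.exp(coefs))
        assert np.allclose(tab["ci_lo"], np.exp(coefs - 1.96 * ses))
        assert np.allclose(tab["ci_hi"], np.exp(coefs + 1.96 * ses))


class TestAssembly:
    def _states(self, times):
        return pd.DataFrame(
            {
                "seal_id": "S0",
                "timestamp": pd.to_datetime(times, utc=True),
                "state": 1,
            }
        )

    def _env(self, dive_ends, depths, chlas):
        n = len(dive_ends)
        return pd.DataFrame(
            {
                "seal_id": "S0",
                "dive_start": pd.to_datetime(dive_ends, utc=True)
                - pd.Timedelta(minutes=5),
                "dive_end": pd.to_datetime(dive_ends, utc=True),
                "T50": 8.0,
                "mld_m": 20.0,
                "la_per_m": 0.1,
                "chla_mg_m3": chlas,
                "bot_depth_m": depths,
                "bot_temp_c": 6.0,
                "bot_dur_s": 120.0,
                "noon": True,
            }
        )

    def test_july_is_summer_january_excluded(self):
        states = self._states(["2014-07-10T12:00:00Z", "2015-01-05T12:00:00Z",
                               "2014-10-01T12:00:00Z"])
        env = self._env(["2014-07-10T11:00:00Z"], [80.0], [1.0])
        obs = glmm.assemble_observations(states, env, {"S0": "F"})
        assert len(obs) == 2  # January step dropped
        assert set(obs["season"]) == {"summer", "fall"}

    def test_window_medians_and_chla_restriction(self):
        """A 30 m dive contributes bottom covariates but no chl-a; the
        60 m noon dive alone defines the step's chl-a."""
        t = "2014-07-10T15:00:00Z"  # 11:00 AST
        states = self._states([t])
        env = self._env(
            [pd.Timestamp(t) - pd.Timedelta(hours=1),
             pd.Timestamp(t) - pd.Timedelta(hours=2)],
            depths=[60.0, 30.0],
            chlas=[1.5, np.nan],  # shallow dive: chl-a undefined
        )
        obs = glmm.assemble_observations(states, env, {"S0": "M"})
        assert obs["chl"].iloc[0] == 1.5
        assert obs["log_bot_depth"].iloc[0] == pytest.approx(np.log(45.0))

    def test_dives_outside_window_ignored(self):
        t = "2014-07-10T12:00:00Z"
        states = self._states([t])
        env = self._env([pd.Timestamp(t) - pd.Timedelta(hours=5)], [80.0], [1.0])
        obs = glmm.assemble_observations(states, env, {"S0": "F"})
        assert np.isnan(obs["chl"].iloc[0])
        assert np.isnan(obs["bot_dur"].iloc[0])

    def test_unknown_sex_is_hard_error(self):
        states = self._states(["2014-07-10T12:00:00Z"])
        env = self._env(["2014-07-10T11:00:00Z"], [80.0], [1.0])
        with pytest.raises(ValueError, match="metadata"):
            glmm.assemble_observations(states, env, {})
        with pytest.raises(ValueError, match="unknown sex"):
            glmm.assemble_observations(states, env, {"S0": "X"})
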