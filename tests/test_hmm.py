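"""DCRW HMM: projection, regularization, likelihood, decoding, fitting."""

import numpy as np
import pandas as pd
import pytest

from sealforage import hmm
from sealforage import synthetic as syn
from oracles import brute_force_loglik, brute_force_viterbi, random_params


def _fix_frame(hours, lons, lats):
    return pd.DataFrame(
        {
            "seal_id": "S0",
            "timestamp": pd.Timestamp("2014-07-01T00:00:00Z")
            + pd.to_timedelta(hours, unit="h"),
            "lon": lons,
            "lat": lats,
            "nsats": 8,
            "residual": 1.0,
        }
    )


class TestProjection:
    def test_centroid_maps_to_origin(self):
        p = hmm.AzimuthalEquidistant(-60.0, 44.0)
        x, y = p.forward(-60.0, 44.0)
        assert (x, y) == (0.0, 0.0)

    def test_one_degree_latitude(self):
        p = hmm.AzimuthalEquidistant(-60.0, 44.0)
        _, y0 = p.forward(-60.0, 44.0)
        _, y1 = p.forward(-60.0, 45.0)
        assert abs(y1 - y0) == pytest.approx(111.2, abs=0.2)

    def test_round_trip(self):
        p = hmm.AzimuthalEquidistant(-60.0, 44.0)
        rng = np.random.default_rng(0)
        lon = -60 + rng.uniform(-3, 3, 50)
        lat = 44 + rng.uniform(-3, 3, 50)
        x, y = p.forward(lon, lat)
        lon2, lat2 = p.inverse(x, y)
        assert np.allclose(lon2, lon, atol=1e-9)
        assert np.allclose(lat2, lat, atol=1e-9)


class TestRegularize:
    def test_on_grid_fixes_unchanged(self):
        fx = _fix_frame([0, 3, 6, 9], [-60.0] * 4, [44.0, 44.1, 44.2, 44.3])
        fx, _ = hmm.project_track(fx)
        out = hmm.regularize_track(fx)
        assert len(out) == 4
        assert np.allclose(out["y_km"], fx["y_km"])

    def test_linear_interpolation_midpoint(self):
        fx = _fix_frame([0, 6], [-60.0, -60.0], [44.0, 44.0])
        fx, _ = hmm.project_track(fx)
        fx.loc[0, ["x_km", "y_km"]] = [0.0, 0.0]
        fx.loc[1, ["x_km", "y_km"]] = [6.0, 0.0]
        out = hmm.regularize_track(fx)
        mid = out[out["timestamp"] == pd.Timestamp("2014-07-01T03:00:00Z")]
        assert np.allclose(mid[["x_km", "y_km"]].to_numpy(), [[3.0, 0.0]])

    def test_long_gap_splits_segments(self):
        hours = [0, 3, 6, 36, 39, 42]  # 30-h gap > 4 * 3 h
        fx = _fix_frame(hours, [-60.0] * 6, 44.0 + 0.01 * np.arange(6))
        out = hmm.regularize_track(fx)
        assert out["segment"].nunique() == 2


class TestLoglik:
    def test_matches_enumeration_on_random_draws(self):
        """Forward log-likelihood equals the 2^T enumeration oracle."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            params = random_params(rng)
            T = int(rng.integers(3, 9))
            d = rng.normal(0, 2.0, (T + 1, 2))
            pos = np.vstack([[0, 0], np.cumsum(d, axis=0)])
            ll = hmm.dcrw_loglik(pos, params)
            assert ll == pytest.approx(brute_force_loglik(d, params), abs=1e-10)

    def test_identical_states_degenerate_mixture(self):
        """Both states identical: the HMM marginal equals the one-state
        Gaussian DCRW likelihood computed directly."""
        params = hmm.HmmParams(
            theta=[0.3, 0.3], gamma=[0.6, 0.6], sigma=[1.5, 1.5],
            A=[[0.7, 0.3], [0.4, 0.6]], delta=[0.5, 0.5],
        )
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 2, (12, 2)), axis=0)
        d = np.diff(pos, axis=0)
        g, th, s = 0.6, 0.3, 1.5
        direct = 0.0
        for i in range(1, len(d)):
            mx = g * (np.cos(th) * d[i - 1, 0] - np.sin(th) * d[i - 1, 1])
            my = g * (np.sin(th) * d[i - 1, 0] + np.cos(th) * d[i - 1, 1])
            r2 = (d[i, 0] - mx) ** 2 + (d[i, 1] - my) ** 2
            direct += -np.log(2 * np.pi * s**2) - r2 / (2 * s**2)
        assert hmm.dcrw_loglik(pos, params) == pytest.approx(direct, abs=1e-10)

    def test_identity_transition_pure_state(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(0, 2, (10, 2)), axis=0)
        base = dict(theta=[0.1, 2.0], gamma=[0.8, 0.2], sigma=[1.0, 3.0])
        p_mix = hmm.HmmParams(**base, A=[[1.0, 0.0], [0.0, 1.0]], delta=[1.0, 0.0])
        p_one = hmm.HmmParams(
            theta=[0.1, 0.1], gamma=[0.8, 0.8], sigma=[1.0, 1.0],
            A=[[0.5, 0.5], [0.5, 0.5]], delta=[1.0, 0.0],
        )
        # state 2 unreachable and never entered -> pure state-1 likelihood
        d = np.diff(pos, axis=0)
        assert hmm.dcrw_loglik(pos, p_mix) == pytest.approx(
            brute_force_loglik(d, p_one), abs=1e-10
        )

    def test_swap_symmetry(self):
        """Relabelling the states leaves the marginal likelihood unchanged."""
        rng = np.random.default_rng(3)
        params = random_params(rng)
        swapped = hmm.HmmParams(
            theta=params.theta[::-1], gamma=params.gamma[::-1],
            sigma=params.sigma[::-1], A=params.A[::-1, ::-1],
            delta=params.delta[::-1],
        )
        pos = np.cumsum(rng.normal(0, 2, (30, 2)), axis=0)
        assert hmm.dcrw_loglik(pos, params) == pytest.approx(
            hmm.dcrw_loglik(pos, swapped), abs=1e-10
        )

    def test_rejects_nonfinite_positions(self):
        params = random_params(np.random.default_rng(4))
        pos = np.cumsum(np.random.default_rng(5).normal(0, 1, (8, 2)), axis=0)
        pos[3, 0] = np.nan
        with pytest.raises(ValueError):
            hmm.dcrw_loglik(pos, params)


class TestDecode:
    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(8):
            params = random_params(rng)
            T = int(rng.integers(3, 9))
            d = rng.normal(0, 2.0, (T + 1, 2))
            pos = np.vstack([[0, 0], np.cumsum(d, axis=0)])
            states, _ = hmm.decode_states(pos, params)
            oracle, _ = brute_force_viterbi(d, params)
            assert np.array_equal(states, oracle)

    def test_absorbing_state_two(self):
        params = hmm.HmmParams(
            theta=[0.0, 0.5], gamma=[0.8, 0.3], sigma=[1.0, 2.0],
            A=[[1.0, 0.0], [0.0, 1.0]], delta=[0.0, 1.0],
        )
        pos = np.cumsum(np.random.default_rng(8).normal(0, 2, (20, 2)), axis=0)
        states, post = hmm.decode_states(pos, params)
        assert (states == 1).all()
        assert np.allclose(post[:, 1], 1.0)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(9)
        params = random_params(rng)
        pos = np.cumsum(rng.normal(0, 2, (200, 2)), axis=0)
        _, post = hmm.decode_states(pos, params)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def sim_track():
    cfg = syn.SimConfig(seed=31, track_steps=1000, theta=(0.0, np.pi))
    tr, st = syn.simulate_track(cfg, "S0")
    return tr, st, cfg


class TestFit:

    def test_parameter_recovery(self, sim_track):
        """Refit on 1000 simulated steps recovers gamma to within 0.05
        per state and separates the turning angles."""
        tr, st, cfg = sim_track
        pos = tr[["x_km", "y_km"]].to_numpy()
        fit = hmm.fit_hmm(pos, n_restarts=6, seed=0)
        assert fit.converged
        assert abs(fit.params.gamma[0] - 0.9) < 0.05
        assert abs(fit.params.gamma[1] - 0.2) < 0.05
        assert abs(hmm.wrap_angle(fit.params.theta[0])) < 0.15
        assert abs(abs(fit.params.theta[1]) - np.pi) < 0.3

    def test_decoding_accuracy(self, sim_track):
        tr, st, cfg = sim_track
        pos = tr[["x_km", "y_km"]].to_numpy()
        fit = hmm.fit_hmm(pos, n_restarts=6, seed=0)
        assert np.mean(fit.states == st) > 0.9

    def test_determinism(self, sim_track):
        tr, _, _ = sim_track
        pos = tr[["x_km", "y_km"]].to_numpy()[:300]
        f1 = hmm.fit_hmm(pos, n_restarts=3, seed=123)
        f2 = hmm.fit_hmm(pos, n_restarts=3, seed=123)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.params.gamma, f2.params.gamma)
        assert np.array_equal(f1.states, f2.states)

    def test_generative_params_beat_perturbed_on_average(self):
        """The likelihood prefers the generating parameters to a
        perturbation, averaged over simulations."""
        cfg = syn.SimConfig(seed=17, track_steps=300)
        true = hmm.HmmParams(
            theta=list(cfg.theta), gamma=list(cfg.gamma),
            sigma=list(cfg.sigma_km), A=np.asarray(cfg.transition),
            delta=[0.5, 0.5],
        )
        pert = hmm.HmmParams(
            theta=[0.5, -0.5], gamma=[0.7, 0.4],
            sigma=[s * 1.5 for s in cfg.sigma_km], A=np.asarray(cfg.transition),
            delta=[0.5, 0.5],
        )
        diffs = []
        for k in range(5):
            tr, _ = syn.simulate_track(cfg, f"S{k}")
            pos = tr[["x_km", "y_km"]].to_numpy()
            diffs.append(hmm.dcrw_loglik(pos, true) - hmm.dcrw_loglik(pos, pert))
        assert np.mean(diffs) > 0

    def test_theta_wrapping(self):
        """Angles near 2 pi are reported near zero."""
        assert hmm.wrap_angle(2 * np.pi - 0.05) == pytest.approx(-0.05)
        assert hmm.wrap_angle(2 * np.pi + 0.05) == pytest.approx(0.05)
        p = hmm.HmmParams(theta=[2 * np.pi - 0.05, 0.0], gamma=[0.8, 0.2],
                          sigma=[1, 1], A=[[0.9, 0.1], [0.1, 0.9]],
                          delta=[0.5, 0.5])
        assert p.theta[0] == pytest.approx(-0.05)

    def test_too_few_steps_rejected(self):
        pos = np.cumsum(np.random.default_rng(1).normal(0, 1, (20, 2)), axis=0)
        with pytest.raises(ValueError, match="usable displacements"):
            hmm.fit_hmm(pos, n_restarts=2, seed=0, min_steps=50)
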