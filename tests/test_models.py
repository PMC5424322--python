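"""Model-family definitions: conversions, moments, VAFs, transitions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvmkit import (
    CVMParams,
    ModelKind,
    eta_to_nu,
    johnson_inverse,
    johnson_map,
    nu_to_eta,
    rotation_scale,
    speed_conversions,
    stationary_moments,
    theoretical_vaf,
    transition,
    transition_van_loan,
)
from conftest import ALL_KIND_PARAMS, random_params


class TestSpeedConversions:
    def test_published_bowhead_value(self):
        # eta = 2.263 km/h corresponds to a mean speed of ~2.005 km/h
        assert eta_to_nu(2.263) == pytest.approx(2.005, abs=2e-3)

    def test_unit_nu(self):
        # 2/sqrt(pi) to five decimals
        assert nu_to_eta(1.0) == pytest.approx(1.12838, abs=5e-6)

    def test_small_eta_limit(self):
        assert eta_to_nu(1e-12) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_bijection(self, x):
        assert nu_to_eta(eta_to_nu(x)) == pytest.approx(x, rel=1e-12)
        assert eta_to_nu(nu_to_eta(x)) == pytest.approx(x, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            speed_conversions(bad, "eta_to_nu")

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            speed_conversions(1.0, "sideways")


class TestStationaryMoments:
    @pytest.mark.parametrize(
        "eta,mu,expected",
        [
            (2.263, (0.0, 0.0), 2.005),   # unbiased phase
            (1.480, (-0.49, -1.44), 1.926),  # advective phase
            (1.361, (1.49, 1.14), 2.144),
            (0.733, (-0.25, -0.24), 0.721),
        ],
    )
    def test_mean_speed_matches_published_phases(self, eta, mu, expected):
        """Rice-mean speed reproduces published bowhead phase values.

        Agreement is limited by the 2-3 decimal rounding of the
        published (eta, mu) inputs, hence the 2e-3 absolute tolerance.
        """
        kind = "ucvm" if mu == (0.0, 0.0) else "acvm"
        m = stationary_moments(CVMParams(kind, 1.0, eta, mu))
        assert m["mean_speed"] == pytest.approx(expected, abs=2e-3)

    def test_mean_sq_speed_decomposition(self):
        m = stationary_moments(CVMParams("ucvm", 2.0, 3.0))
        assert m["mean_sq_speed"] == pytest.approx(9.0)
        m = stationary_moments(CVMParams("acvm", 2.0, 3.0, (2.0, 0.0)))
        assert m["mean_sq_speed"] == pytest.approx(13.0)

    def test_unbiased_mean_speed_is_nu(self):
        p = CVMParams("ucvm", 1.0, 3.0)
        assert stationary_moments(p)["mean_speed"] == pytest.approx(eta_to_nu(3.0), rel=1e-12)

    def test_monte_carlo_mean_speed(self):
        # Rice mean against direct simulation of the stationary velocity
        rng = np.random.default_rng(0)
        p = CVMParams("acvm", 1.0, 1.48, (-0.49, -1.44))
        v = np.array(p.mu) + (p.eta / math.sqrt(2)) * rng.standard_normal((200_000, 2))
        mc = np.mean(np.hypot(v[:, 0], v[:, 1]))
        assert stationary_moments(p)["mean_speed"] == pytest.approx(mc, rel=5e-3)


class TestTheoreticalVAF:
    def test_lag_zero_equals_mean_sq_speed(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_params(rng)
            v0 = theoretical_vaf(p, [0.0])[0]
            assert v0 == pytest.approx(stationary_moments(p)["mean_sq_speed"], rel=1e-12)

    def test_asymptotes(self):
        assert theoretical_vaf(ALL_KIND_PARAMS["ucvm"], [1e6])[0] == pytest.approx(0.0, abs=1e-12)
        assert theoretical_vaf(ALL_KIND_PARAMS["acvm"], [1e6])[0] == pytest.approx(4.0)

    def test_rotational_value_at_half_period(self):
        # eta^2 e^{-dt/tau} cos(omega dt) at omega*dt = pi
        p = ALL_KIND_PARAMS["rcvm"]
        lag = math.pi / 2.0
        expected = 9.0 * math.exp(-lag / 5.0) * math.cos(2.0 * lag)
        got = theoretical_vaf(p, [lag])[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-6.5736, abs=1e-4)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            theoretical_vaf(ALL_KIND_PARAMS["ucvm"], [-0.1])


class TestTransition:
    def test_degenerate_interval_limits(self):
        p = ALL_KIND_PARAMS["racvm"]
        st_ = transition(p, 1e-10)
        assert np.allclose(st_.transition, np.eye(4), atol=1e-8)
        assert np.allclose(st_.drift, 0.0, atol=1e-8)
        assert np.allclose(st_.noise_cov, 0.0, atol=1e-8)

    def test_long_interval_velocity_stationarity(self):
        p = ALL_KIND_PARAMS["ucvm"]
        st_ = transition(p, 1000.0)
        vel = st_.transition[np.ix_([1, 3], [1, 3])]
        assert np.allclose(vel, 0.0, atol=1e-12)
        # velocity innovation variance per component -> eta^2 / 2
        assert st_.noise_cov[1, 1] == pytest.approx(p.eta**2 / 2.0, rel=1e-12)
        assert st_.noise_cov[3, 3] == pytest.approx(p.eta**2 / 2.0, rel=1e-12)

    def test_half_turn_rotation_block(self):
        # omega * dt = pi: the velocity block is -e^{-dt/tau} I
        p = ALL_KIND_PARAMS["rcvm"]
        dt = math.pi / 2.0
        st_ = transition(p, dt)
        vel = st_.transition[np.ix_([1, 3], [1, 3])]
        assert np.allclose(vel, -math.exp(-dt / 5.0) * np.eye(2), atol=1e-12)

    def test_closed_form_omega_zero(self):
        # printed per-component closed forms for the integrated OU
        tau, eta, dt = 5.0, 3.0, 0.7
        st_ = transition(CVMParams("ucvm", tau, eta), dt)
        th = 1.0 / tau
        var_vv = eta**2 / 2 * (1 - math.exp(-2 * th * dt))
        cov_zv = eta**2 * tau / 2 * (1 - math.exp(-th * dt)) ** 2
        var_zz = (eta**2 * tau * dt - 2 * eta**2 * tau**2 * (1 - math.exp(-th * dt))
                  + eta**2 * tau**2 / 2 * (1 - math.exp(-2 * th * dt)))
        assert st_.noise_cov[1, 1] == pytest.approx(var_vv, rel=1e-12)
        assert st_.noise_cov[0, 1] == pytest.approx(cov_zv, rel=1e-12)
        assert st_.noise_cov[0, 0] == pytest.approx(var_zz, rel=1e-12)

    def test_matches_matrix_exponential_oracle(self):
        """Closed forms agree with the brute-force Van Loan construction.

        Restricted to dt/tau <= 8: beyond that the Van Loan block
        matrix contains e^{+dt/tau} and the *oracle* loses precision.
        """
        rng = np.random.default_rng(11)
        for _ in range(60):
            p = random_params(rng)
            dt = float(10 ** rng.uniform(-2, math.log10(8.0 * p.tau)))
            a = transition(p, dt)
            b = transition_van_loan(p, dt)
            scale = 1.0 + np.max(np.abs(b.noise_cov))
            assert np.allclose(a.transition, b.transition, atol=1e-8)
            assert np.allclose(a.drift, b.drift, atol=1e-8)
            assert np.max(np.abs(a.noise_cov - b.noise_cov)) / scale < 1e-8

    def test_noise_cov_psd(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = random_params(rng)
            st_ = transition(p, float(10 ** rng.uniform(-2, 1)))
            assert np.allclose(st_.noise_cov, st_.noise_cov.T)
            assert np.min(np.linalg.eigvalsh(st_.noise_cov)) >= -1e-10

    def test_racvm_nests_acvm_at_omega_zero(self):
        acvm = CVMParams("acvm", 3.0, 2.0, (1.0, -0.5))
        racvm = CVMParams("racvm", 3.0, 2.0, (1.0, -0.5), omega=0.0)
        a, r = transition(acvm, 0.8), transition(racvm, 0.8)
        assert np.array_equal(a.transition, r.transition)
        assert np.array_equal(a.noise_cov, r.noise_cov)
        assert np.array_equal(a.drift, r.drift)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            transition(ALL_KIND_PARAMS["ucvm"], 0.0)


class TestJohnsonMap:
    def test_published_mapping(self):
        m = johnson_map(CVMParams("ucvm", 10.0, 2.0))
        assert m == {"beta_J": pytest.approx(0.1), "sigma2_J": pytest.approx(0.4)}

    def test_identity_scale(self):
        m = johnson_map(CVMParams("ucvm", 1.0, 1.0))
        assert m == {"beta_J": 1.0, "sigma2_J": 1.0}

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_params(rng, "ucvm")
            m = johnson_map(p)
            tau, eta = johnson_inverse(m["beta_J"], m["sigma2_J"])
            assert tau == pytest.approx(p.tau, rel=1e-12)
            assert eta == pytest.approx(p.eta, rel=1e-12)


class TestRotationScale:
    def test_definition(self):
        assert rotation_scale(ALL_KIND_PARAMS["rcvm"]) == pytest.approx(1.5)

    def test_small_eta_limit(self):
        assert rotation_scale(CVMParams("rcvm", 1.0, 1e-9, omega=2.0)) == pytest.approx(0.0, abs=1e-9)

    def test_undefined_without_rotation(self):
        with pytest.raises(ValueError):
            rotation_scale(ALL_KIND_PARAMS["ucvm"])


class TestCVMParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "ucvm", "tau": -1.0, "eta": 1.0},
            {"kind": "ucvm", "tau": 1.0, "eta": 0.0},
            {"kind": "ucvm", "tau": 1.0, "eta": 1.0, "mu": (1.0, 0.0)},
            {"kind": "acvm", "tau": 1.0, "eta": 1.0, "omega": 1.0},
            {"kind": "rcvm", "tau": 1.0, "eta": 1.0, "mu": (0.0, 1.0)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CVMParams(**kwargs)

    def test_parameter_counts(self):
        assert [ALL_KIND_PARAMS[k].n_params for k in ("ucvm", "acvm", "rcvm", "racvm")] == [2, 4, 3, 5]

    def test_record_round_trip_bit_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = random_params(rng)
            q = CVMParams.from_record(p.to_record())
            assert q == p
            r = CVMParams.from_json(p.to_json())
            assert r == p
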