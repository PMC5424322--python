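"""Parameter estimation: ML fits, CRW matching, selection, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cvmkit import (
    CVMFitter,
    CVMParams,
    Track,
    crw_match,
    crw_summary,
    fit_cvm,
    select_model,
    simulate,
    subsample_random,
    subsample_stability,
)
from conftest import ALL_KIND_PARAMS


class TestCRWSummary:
    def test_collinear_equal_steps(self):
        t = np.arange(10.0)
        tr = Track(t=t, x=2.0 * t, y=np.zeros_like(t))
        s = crw_summary(tr)
        assert s.kappa == pytest.approx(1.0)
        assert s.lam == pytest.approx(0.0, abs=1e-12)
        assert s.mean_step == pytest.approx(2.0)

    def test_perfect_reversals(self):
        t = np.arange(10.0)
        x = np.array([0.0, 1.0] * 5)
        tr = Track(t=t, x=x, y=np.zeros_like(t))
        assert crw_summary(tr).kappa == pytest.approx(-1.0)

    def test_coarse_ucvm_turning_angle_persistence(self):
        """Mean turn cosine matches the exact integrated-OU prediction.

        Successive displacements of a stationary UCVM are jointly
        Gaussian with per-component correlation

            rho = [h^2 (eta^2/2) e^{-x} + h (eta^2 tau/2)(1-e^{-x})^2] / sd^2,

        h = tau(1-e^{-x}), x = dt/tau, and the mean cosine of the angle
        between two such vectors is (pi rho / 4) 2F1(1/2, 1/2; 2; rho^2).
        (Exceeds the raw velocity autocorrelation e^{-x}: integration
        smooths the steps.)
        """
        from scipy.special import hyp2f1

        tau, eta, dt = 5.0, 2.0, 5.0
        x = dt / tau
        h = tau * (1 - math.exp(-x))
        var = (eta**2 * tau * dt + 2 * eta**2 * tau**2 * (math.exp(-x) - 1)
               + eta**2 * tau**2 / 2 * (1 - math.exp(-2 * x)) + h**2 * eta**2 / 2)
        cov = h**2 * (eta**2 / 2) * math.exp(-x) + h * (eta**2 * tau / 2) * (1 - math.exp(-x)) ** 2
        rho = cov / var
        kappa_theory = (math.pi * rho / 4.0) * hyp2f1(0.5, 0.5, 2.0, rho**2)
        p = CVMParams("ucvm", tau, eta)
        kappas = [crw_summary(simulate(p, n=800, dt=dt, seed=s)).kappa for s in range(10)]
        assert np.mean(kappas) == pytest.approx(kappa_theory, abs=0.02)


class TestCRWMatch:
    def test_inverts_autocorrelation_rule(self):
        from cvmkit.fitting import CRWSummary

        s = CRWSummary(lam=1.0, kappa=math.exp(-1.0), mean_dt=1.0, mean_step=1.0, n_steps=100)
        fr = crw_match(s)
        assert fr.params.tau == pytest.approx(1.0, rel=1e-12)
        assert fr.likelihood_method == "crw"

    def test_rough_speed_recovery(self):
        # nu-hat within 30% of truth on coarsely sampled tracks (an
        # acknowledged rough approximation)
        from cvmkit import eta_to_nu

        p = CVMParams("ucvm", 5.0, eta=2.0 * 2.0 / math.sqrt(math.pi))  # nu = 2
        nus = []
        for s in range(50):
            tr = simulate(p, n=200, dt=5.0, seed=100 + s)
            fr = crw_match(crw_summary(tr))
            nus.append(eta_to_nu(fr.params.eta))
        assert abs(np.mean(nus) - 2.0) / 2.0 < 0.3

    def test_negative_persistence_rejected(self):
        from cvmkit.fitting import CRWSummary

        s = CRWSummary(lam=1.0, kappa=-0.5, mean_dt=1.0, mean_step=1.0, n_steps=100)
        with pytest.raises(ValueError):
            crw_match(s)

    def test_kappa_near_one_capped_with_warning(self):
        from cvmkit.fitting import CRWSummary

        s = CRWSummary(lam=0.1, kappa=1.0, mean_dt=1.0, mean_step=1.0, n_steps=100)
        with pytest.warns(RuntimeWarning):
            fr = crw_match(s)
        assert math.isfinite(fr.params.tau)


class TestFitCVM:
    def test_noiseless_limit_recovers_drift(self):
        p = CVMParams("acvm", tau=2.0, eta=1e-6, mu=(1.5, -0.5))
        tr = simulate(p, n=100, dt=0.1, v0=(1.5, -0.5), seed=0)
        fr = fit_cvm(tr, "acvm", ci_method="none")
        assert fr.params.mu[0] == pytest.approx(1.5, abs=1e-4)
        assert fr.params.mu[1] == pytest.approx(-0.5, abs=1e-4)

    def test_information_criteria_definitions(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=100, dt=0.1, seed=1)
        fr = fit_cvm(tr, "ucvm", ci_method="none")
        assert fr.n_eff == len(tr) - 1
        assert fr.bic == pytest.approx(-2 * fr.loglik + 2 * math.log(fr.n_eff))
        assert fr.aic == pytest.approx(-2 * fr.loglik + 4)

    def test_ci_brackets_point_estimate(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=300, dt=0.5, seed=2)
        fr = fit_cvm(tr, "ucvm", ci_method="profile")
        for name, value in (("tau", fr.params.tau), ("eta", fr.params.eta)):
            lo, hi = fr.ci[name]
            assert lo < value < hi

    def test_too_short_track_rejected(self):
        tr = Track(t=np.arange(5.0), x=np.random.default_rng(0).normal(size=5), y=np.zeros(5))
        with pytest.raises(ValueError):
            fit_cvm(tr, "ucvm")


class TestSelectModel:
    def test_single_candidate_trivial(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=120, dt=0.5, seed=3)
        tab = select_model(tr, ["ucvm"], ci_method="none")
        assert list(tab.index) == ["ucvm"]
        assert tab["delta"].iloc[0] == 0.0

    def test_rotational_signal_dominates(self, dense_racvm_track):
        tr = subsample_random(dense_racvm_track, 400, seed=1)
        tab = select_model(tr, ci_method="none")
        rot = tab.loc[["rcvm", "racvm"], "delta"].min()
        nonrot = tab.loc[["ucvm", "acvm"], "delta"].min()
        assert nonrot > rot + 10.0

    def test_quartet_mostly_selected(self, quartet_params):
        """At least 3 of the 4 canonical designs select their true kind."""
        hits = 0
        for kind, p in quartet_params.items():
            tr = subsample_random(simulate(p, n=500, dt=0.01, seed=77), 400, seed=78)
            tab = select_model(tr, ci_method="none")
            hits += tab.index[0] == kind
        assert hits >= 3

    def test_criterion_validation(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=50, dt=0.5, seed=0)
        with pytest.raises(ValueError):
            select_model(tr, criterion="dic")


class TestCVMFitterAPI:
    def test_sklearn_contract(self):
        est = CVMFitter(kind="ucvm", likelihood="velocity", ci_method="none")
        params = est.get_params()
        assert params["kind"] == "ucvm"
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(kind="acvm")
        assert est.kind == "acvm"

    def test_fit_sets_attributes(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=200, dt=0.5, seed=9)
        est = CVMFitter(kind="ucvm", ci_method="none").fit(tr)
        assert est.params_.kind.value == "ucvm"
        assert math.isfinite(est.loglik_) and math.isfinite(est.bic_)
        assert est.score(tr) == pytest.approx(est.loglik_)

    def test_auto_selection_table(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=150, dt=0.5, seed=10)
        est = CVMFitter(kind="auto", ci_method="none").fit(tr)
        assert hasattr(est, "selection_table_")
        assert est.params_.kind.value == est.selection_table_.index[0]

    def test_accepts_dataframe_and_array(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=100, dt=0.5, seed=11)
        df = pd.DataFrame({"t": tr.t, "x": tr.x, "y": tr.y})
        arr = np.column_stack([tr.t, tr.x, tr.y])
        f1 = CVMFitter(kind="ucvm", ci_method="none").fit(df)
        f2 = CVMFitter(kind="ucvm", ci_method="none").fit(arr)
        assert f1.params_.tau == pytest.approx(f2.params_.tau)


class TestSubsampleStability:
    def test_full_length_equals_direct_fit(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=300, dt=0.5, seed=12)
        tab = subsample_stability(tr, [len(tr)], reps=1, seed=0, ci_method="none")
        direct = fit_cvm(tr, "ucvm", ci_method="none")
        assert tab["tau"].iloc[0] == pytest.approx(direct.params.tau)

    def test_table_layout_and_ci_behavior(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=400, dt=0.5, seed=13)
        tab = subsample_stability(tr, [100, 200, 400], reps=2, seed=1, ci_method="profile")
        assert set(tab.columns) >= {"n", "mean_dt", "tau", "tau_lo", "tau_hi", "nu", "nu_lo", "nu_hi"}
        width = tab.groupby("n").apply(
            lambda g: np.mean(np.log(g.tau_hi) - np.log(g.tau_lo)), include_groups=False)
        # CI width non-increasing in n on average
        assert width.loc[400] <= width.loc[100] + 1e-9

    def test_oversized_grid_rejected(self):
        tr = simulate(ALL_KIND_PARAMS["ucvm"], n=100, dt=0.5, seed=14)
        with pytest.raises(ValueError):
            subsample_stability(tr, [200], seed=0)
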