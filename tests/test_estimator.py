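"""Pseudo-outcome construction, dose-response regression and model classes."""

import numpy as np
import pytest

from goalder.ensembles import fit_outcome_ensemble
from goalder.estimator import (
    GOALDeR,
    SLDR,
    PseudoOutcome,
    bootstrap_sd,
    build_pseudo_outcome,
    estimate_goaldr,
    estimate_sldr,
    regress_drf,
)
from goalder.simulate import ScenarioSpec, generate_dataset

from conftest import random_weight_vector


class _LinearFit:
    """Closed-form stand-in outcome model mu(z, t) = c0 + c'z + c_t t."""

    def __init__(self, c0, cz, ct):
        self.c0, self.cz, self.ct = c0, np.atleast_1d(cz), ct
        self.n_features = self.cz.size + 1


def _linear_predict_matrix(fit, z, t_values):
    out = np.empty((z.shape[0], t_values.size))
    for k in range(z.shape[0]):
        for i in range(t_values.size):
            out[k, i] = fit.c0 + fit.cz @ z[k] + fit.ct * t_values[i]
    return out


@pytest.fixture
def patched_linear_mu(monkeypatch):
    """Route the pseudo-outcome's predictions through the closed-form model."""
    import goalder.estimator as est

    def fake_matrix(fit, z, t_values):
        return _linear_predict_matrix(fit, np.atleast_2d(z), np.asarray(t_values))

    def fake_point(fit, z, t):
        z = np.atleast_2d(z)
        t = np.asarray(t, float).ravel()
        return np.array([fit.c0 + fit.cz @ z[k] + fit.ct * t[k] for k in range(len(t))])

    monkeypatch.setattr(est, "predict_outcome_matrix", fake_matrix)
    monkeypatch.setattr(est, "predict_outcome", fake_point)


class TestBuildPseudoOutcome:
    def test_exact_model_no_covariates_recovers_2t(self, rng, patched_linear_mu):
        n = 12
        t = rng.standard_normal(n)
        y = 2.0 * t
        z = np.zeros((n, 1))
        fit = _LinearFit(0.0, [0.0], 2.0)
        w = random_weight_vector(rng, n)
        pseudo = build_pseudo_outcome(fit, t, y, z, w)
        assert np.allclose(pseudo.theta, 2.0 * t, atol=1e-12)

    def test_zero_model_unit_weights_returns_outcome(self, rng, patched_linear_mu):
        n = 9
        t = rng.standard_normal(n)
        y = rng.standard_normal(n)
        z = rng.standard_normal((n, 2))
        fit = _LinearFit(0.0, [0.0, 0.0], 0.0)
        pseudo = build_pseudo_outcome(fit, t, y, z, np.ones(n))
        assert np.allclose(pseudo.theta, y, atol=1e-12)

    def test_matches_hand_computed_double_loop(self, patched_linear_mu):
        rng = np.random.default_rng(21)
        n = 6
        t = rng.standard_normal(n)
        y = rng.standard_normal(n)
        z = rng.standard_normal((n, 2))
        w = random_weight_vector(rng, n)
        fit = _LinearFit(0.3, [1.0, -0.5], 0.8)

        def mu(zrow, tval):
            return 0.3 + zrow @ np.array([1.0, -0.5]) + 0.8 * tval

        expected = np.empty(n)
        for i in range(n):
            term1 = np.mean([mu(z[k], t[i]) for k in range(n)])
            expected[i] = term1 + (y[i] - mu(z[i], t[i])) * w[i]

        pseudo = build_pseudo_outcome(fit, t, y, z, w)
        assert np.allclose(pseudo.theta, expected, atol=1e-10)

    def test_recomposition_identity(self, rng, patched_linear_mu):
        n = 8
        t = rng.standard_normal(n)
        y = rng.standard_normal(n)
        z = rng.standard_normal((n, 2))
        w = random_weight_vector(rng, n)
        pseudo = build_pseudo_outcome(fit := _LinearFit(0.1, [0.2, 0.3], 1.0), t, y, z, w)
        assert np.allclose(pseudo.theta, pseudo.term1 + pseudo.term2, atol=1e-12)

    def test_real_ensemble_recomposition(self, rng):
        n = 50
        z = rng.standard_normal((n, 2))
        t = rng.standard_normal(n)
        y = z[:, 0] + 2.0 * t + 0.1 * rng.standard_normal(n)
        fit = fit_outcome_ensemble(z, t, y, learners=("lasso",), seed=0)
        pseudo = build_pseudo_outcome(fit, t, y, z, np.ones(n))
        assert np.allclose(pseudo.theta, pseudo.term1 + pseudo.term2, atol=1e-12)


class TestRegressDrf:
    def test_exact_line_recovered(self):
        t = np.linspace(-2, 2, 20)
        res = regress_drf(2.0 * t, t)
        assert res.params[1] == pytest.approx(2.0, abs=1e-12)
        assert res.params[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_pseudo_outcome_zero_slope(self):
        t = np.linspace(0, 1, 15)
        res = regress_drf(np.full(15, 5.0), t)
        assert res.params[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(31)
        t = rng.standard_normal(10)
        theta = 1.5 * t + rng.standard_normal(10)
        res = regress_drf(theta, t)
        tc = t - t.mean()
        slope = (tc @ (theta - theta.mean())) / (tc @ tc)
        resid = theta - (theta.mean() - slope * t.mean()) - slope * t
        se = np.sqrt(resid @ resid / (10 - 2) / (tc @ tc))
        assert res.params[1] == pytest.approx(slope, abs=1e-10)
        assert res.bse[1] == pytest.approx(se, abs=1e-10)

    def test_constant_treatment_rejected(self):
        with pytest.raises(ValueError):
            regress_drf(np.arange(5.0), np.ones(5))


class TestGoalderModel:
    def test_no_covariates_rejected(self, rng):
        with pytest.raises(ValueError, match="covariates"):
            GOALDeR(rng.standard_normal(40), rng.standard_normal(40), None)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            GOALDeR(
                rng.standard_normal(10),
                rng.standard_normal(10),
                rng.standard_normal((10, 3)),
            )

    def test_fit_is_deterministic_given_seed(self, sost_small):
        kwargs = dict(fast=True, seed=11)
        r1 = GOALDeR(sost_small.t, sost_small.y, sost_small.z, **kwargs).fit()
        r2 = GOALDeR(sost_small.t, sost_small.y, sost_small.z, **kwargs).fit()
        assert r1.slope == r2.slope
        assert r1.analytic_sd == r2.analytic_sd
        assert np.array_equal(r1.selected, r2.selected)

    def test_results_surface(self, sost_small):
        res = estimate_goaldr(sost_small.t, sost_small.y, sost_small.z, fast=True)
        assert res.method == "GOALDeR"
        assert res.analytic_sd > 0.0
        ci = res.conf_int()
        assert ci[1, 0] < res.slope < ci[1, 1]
        assert isinstance(res.summary(), str) and "GOALDeR" in res.summary()
        assert res.dwdc_trace() is not None and len(res.dwdc_trace()) == 10
        assert set(res.selected_covariates) <= set(sost_small.covariate_names)

    def test_parameter_recovery_linear_settings(self):
        # moderate-scale check; the simulation study revisits this at scale
        ests = []
        for seed in range(8):
            tri = generate_dataset(ScenarioSpec("SoSt", n=400, p=10, seed=40 + seed))
            ests.append(
                estimate_goaldr(tri.t, tri.y, tri.z, fast=True, seed=seed).slope
            )
        assert abs(np.mean(ests) - 2.0) < 0.1

    def test_null_effect_recovered(self):
        ests = []
        for seed in range(8):
            tri = generate_dataset(
                ScenarioSpec("SoSt", n=400, p=10, eta=0.0, seed=60 + seed)
            )
            ests.append(
                estimate_goaldr(tri.t, tri.y, tri.z, fast=True, seed=seed).slope
            )
        assert abs(np.mean(ests)) < 0.1


class TestSldrModel:
    def test_independent_covariates_recover_slope(self):
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(70 + seed)
            n = 300
            z = rng.standard_normal((n, 4))
            t = rng.standard_normal(n)
            y = 2.0 * t + rng.standard_normal(n)
            res = estimate_sldr(t, y, z, learners=("lasso",), seed=seed)
            ests.append(res.slope)
            w = np.asarray(res.weights)
            # CV-lasso fits a little noise, so weights are near (not exactly) 1
            assert w.mean() == pytest.approx(1.0, abs=1e-8)
            assert w.std() < 0.35
        assert abs(np.mean(ests) - 2.0) < 0.1

    def test_deterministic_given_seed(self, sost_small):
        kwargs = dict(fast=True, seed=4)
        r1 = SLDR(sost_small.t, sost_small.y, sost_small.z, **kwargs).fit()
        r2 = SLDR(sost_small.t, sost_small.y, sost_small.z, **kwargs).fit()
        assert r1.slope == r2.slope

    def test_sost_recovery(self, sost_small):
        res = estimate_sldr(sost_small.t, sost_small.y, sost_small.z, fast=True)
        assert res.method == "SL-DR"
        assert abs(res.slope - 2.0) < 0.4


class TestBootstrap:
    def test_near_degenerate_data_has_tiny_spread(self):
        rng = np.random.default_rng(90)
        n = 200
        z = rng.standard_normal((n, 4))
        t = z[:, 0] + rng.standard_normal(n)
        y = 2.0 * t + 0.01 * rng.standard_normal(n) + z[:, 0] * 0.0
        boot = bootstrap_sd(t, y, z, method="goaldr", B=50, seed=1, fast=True)
        assert boot.boot_sd < 0.02
        assert boot.n_failed == 0

    def test_noisy_fixture_positive_sd_and_determinism(self, sost_small):
        res = GOALDeR(sost_small.t, sost_small.y, sost_small.z, fast=True).fit()
        b1 = res.bootstrap(B=8, seed=3)
        b2 = GOALDeR(sost_small.t, sost_small.y, sost_small.z, fast=True).fit().bootstrap(
            B=8, seed=3
        )
        assert b1.boot_sd > 0.0
        assert b1.boot_sd == b2.boot_sd
        assert b1.ci_percentile[0] <= b1.ci_percentile[1]

    def test_from_dataframe_roundtrip(self, sost_small):
        df = sost_small.to_dataframe()
        model = GOALDeR.from_dataframe(df, fast=True)
        assert model.data.p == sost_small.p
        assert np.allclose(model.data.t, sost_small.t)
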