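import numpy as np
import pytest

from idmspec import full_structure, prediction
from idmspec.cox_engine import CoxError, StepHazard
from idmspec.prediction import (
    constant_hazard_model,
    microsimulate,
    model_from_step_hazards,
    overall_survival,
    predict_from_healthy,
    predict_from_progression,
)

L01, L02, L12 = 0.1, 0.05, 0.2


def closed_form(t, l01=L01, l02=L02, l12=L12):
    """Constant-hazard illness-death solution from the healthy state."""
    t = np.asarray(t, float)
    p00 = np.exp(-(l01 + l02) * t)
    p01 = l01 / (l01 + l02 - l12) * (np.exp(-l12 * t) - np.exp(-(l01 + l02) * t))
    return p00, p01, 1.0 - p00 - p01


@pytest.fixture(scope="module")
def const_model():
    return constant_hazard_model(L01, L02, L12, horizon=12.0, dt=0.005)


class TestFromHealthy:
    def test_starts_at_degenerate_distribution(self, const_model):
        sp = predict_from_healthy(const_model, {}, np.array([0.0]))
        assert sp["P00"][0] == 1.0
        assert sp["P01"][0] == 0.0
        assert sp["P02"][0] == 0.0

    def test_matches_constant_hazard_closed_form(self, const_model):
        t = np.array([2.0, 5.0, 10.0])
        sp = predict_from_healthy(const_model, {}, t)
        p00, p01, p02 = closed_form(t)
        np.testing.assert_allclose(sp["P00"], p00, atol=1e-3)
        np.testing.assert_allclose(sp["P01"], p01, atol=1e-3)
        np.testing.assert_allclose(sp["P02"], p02, atol=1e-3)

    def test_mass_conventions_agree_at_fine_steps(self, const_model):
        t = np.linspace(0, 10, 11)
        a = predict_from_healthy(const_model, {}, t, mass="discrete")
        b = predict_from_healthy(const_model, {}, t, mass="hazard")
        np.testing.assert_allclose(a["P01"], b["P01"], atol=2e-3)

    def test_missing_profile_covariate_raises(self, fitted_full):
        with pytest.raises(CoxError, match="age"):
            predict_from_healthy(fitted_full, {"residual_tumor": 1}, np.array([1.0]))


class TestFromProgression:
    def test_starts_in_progression_state(self, const_model):
        sp = predict_from_progression(const_model, {"t010": 10.0}, np.array([0.0]))
        assert sp["P11"][0] == 1.0
        assert sp["P12"][0] == 0.0

    def test_constant_hazard_exponential_survival(self, const_model):
        sp = predict_from_progression(const_model, {"t010": 3.0}, np.array([5.0]))
        assert sp["P11"][0] == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_longer_healthy_sojourn_improves_prognosis(self, fitted_full, profile_b):
        # the fitted t010 log-hazard slope is negative, so P11 rises in t010
        s = np.array([6.0, 12.0, 24.0])
        early = predict_from_progression(fitted_full, {**profile_b, "t010": 6.0}, s)
        late = predict_from_progression(fitted_full, {**profile_b, "t010": 36.0}, s)
        assert fitted_full.t010_coef < 0
        assert (late["P11"] > early["P11"]).all()

    def test_requires_t010(self, const_model):
        with pytest.raises(CoxError, match="t010"):
            predict_from_progression(const_model, {}, np.array([1.0]))


class TestMicrosimulate:
    def test_reproducible_under_fixed_seed(self, const_model):
        g = np.linspace(0, 10, 6)
        a = microsimulate(const_model, {}, g, n_paths=5000, seed=42)
        b = microsimulate(const_model, {}, g, n_paths=5000, seed=42)
        for k in a.probs:
            np.testing.assert_array_equal(a[k], b[k])

    def test_single_path_is_deterministic_indicator(self, const_model):
        g = np.linspace(0, 10, 6)
        sp = microsimulate(const_model, {}, g, n_paths=1, seed=0)
        total = np.stack([sp[k] for k in ("P00", "P01", "P02")])
        assert set(np.unique(total)) <= {0.0, 1.0}

    def test_constant_hazard_p01_within_binomial_error(self, const_model):
        n = 200_000
        sp = microsimulate(const_model, {}, np.array([10.0]), n_paths=n, seed=3)
        p = closed_form(10.0)[1]
        assert abs(sp["P01"][0] - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-3

    @pytest.mark.parametrize("seed", [11, 12])
    def test_agrees_with_convolution_on_fitted_models(self, fitted_full, profile_b, seed):
        # the analytic convolution and the path sampler must describe the
        # same fitted law, including the t010 feedback on the 1->2 hazard
        n = 200_000
        g = np.array([6.0, 12.0, 24.0, 48.0])
        sp = predict_from_healthy(fitted_full, profile_b, g)
        ms = microsimulate(fitted_full, profile_b, g, n_paths=n, seed=seed)
        for k in ("P00", "P01", "P02"):
            mc_se = np.sqrt(np.clip(sp[k] * (1 - sp[k]), 1e-12, None) / n)
            assert (np.abs(ms[k] - sp[k]) <= 3 * mc_se + 1e-12).all(), k


class TestOverallSurvival:
    def test_one_at_time_zero(self, const_model):
        assert overall_survival(const_model, {}, np.array([0.0]))[0] == 1.0

    def test_constant_hazard_value(self, const_model):
        s = overall_survival(const_model, {}, np.array([10.0]))[0]
        p00, p01, _ = closed_form(10.0)
        assert s == pytest.approx(p00 + p01, abs=2e-3)

    def test_nonincreasing_on_fitted_model(self, fitted_full, profile_b):
        t = np.linspace(0, 60, 61)
        s = overall_survival(fitted_full, profile_b, t)
        assert (np.diff(s) <= 1e-12).all()


class TestInvariants:
    @pytest.mark.parametrize("profile_key", ["good", "bad"])
    def test_normalization_and_monotonicity(self, fitted_full, profile_key):
        profile = (
            {"age": 50.0, "residual_tumor": 0, "figo_high": 0}
            if profile_key == "good"
            else {"age": 70.0, "residual_tumor": 1, "figo_high": 1}
        )
        t = np.linspace(0, 90, 91)
        sp = predict_from_healthy(fitted_full, profile, t)
        total = sp["P00"] + sp["P01"] + sp["P02"]
        np.testing.assert_allclose(total, 1.0, atol=1e-8)
        assert ((sp["P00"] >= 0) & (sp["P00"] <= 1)).all()
        assert (np.diff(sp["P00"]) <= 1e-12).all()
        assert (np.diff(sp["P02"]) >= -1e-12).all()

    def test_markov_special_case_matches_analytic_solution(self):
        # no sojourn-time effect and constant hazards: the clock reset is
        # irrelevant and the classical Markov solution applies
        mdl = constant_hazard_model(0.08, 0.03, 0.15, horizon=15.0, dt=0.002)
        t = np.linspace(0.5, 12, 10)
        sp = predict_from_healthy(mdl, {}, t)
        p00, p01, p02 = closed_form(t, 0.08, 0.03, 0.15)
        np.testing.assert_allclose(sp["P00"], p00, atol=1e-3)
        np.testing.assert_allclose(sp["P01"], p01, atol=1e-3)
        np.testing.assert_allclose(sp["P02"], p02, atol=1e-3)

    def test_sojourn_feedback_model_convolution_vs_simulation(self):
        # Weibull baselines plus a real t010 effect: only the oracle
        # simulation can validate the convolution here
        t = np.arange(0.05, 30.0, 0.05)
        b01 = StepHazard(t, np.diff(np.concatenate([[0], (t / 20.0) ** 1.3])))
        b02 = StepHazard(t, np.diff(np.concatenate([[0], t / 80.0])))
        b12 = StepHazard(t, np.diff(np.concatenate([[0], (t / 15.0) ** 1.1])))
        mdl = model_from_step_hazards(b01, b02, b12, t010_coef=-0.05)
        g = np.array([5.0, 10.0, 20.0])
        sp = predict_from_healthy(mdl, {"t010": 0.0}, g)
        n = 200_000
        ms = microsimulate(mdl, {"t010": 0.0}, g, n_paths=n, seed=2)
        for k in ("P00", "P01", "P02"):
            mc_se = np.sqrt(np.clip(sp[k] * (1 - sp[k]), 1e-12, None) / n)
            assert (np.abs(ms[k] - sp[k]) <= 3 * mc_se + 1e-12).all(), k
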