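import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize_scalar

from idmspec import cox_engine, full_structure, generate, msdata, paper_like_config
from idmspec.cox_engine import (
    CoxError,
    StepHazard,
    _loglik_parts,
    _split_strata,
    design_matrix,
    fit,
    loglog_curves,
    lr_test,
    schoenfeld_ph_test,
)
from idmspec.structures import Effect, EffectStructure

from conftest import ONE_STRATUM, toy_table


def one_stratum_structure(covariates=("x",)):
    return EffectStructure(
        effects=tuple(Effect(c, frozenset({"01"})) for c in covariates),
        baseline_strata=ONE_STRATUM,
    )


def brute_force_loglik(times, status, X, beta):
    """Breslow log partial likelihood by explicit risk-set enumeration."""
    times = np.asarray(times, float)
    X = np.atleast_2d(np.asarray(X, float).T).T
    ll = 0.0
    for i in np.flatnonzero(status):
        risk = times >= times[i]
        ll += X[i] @ beta - np.log(np.exp(X[risk] @ beta).sum())
    return ll


class TestPartialLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration_on_tiny_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        times = rng.exponential(10, n).round(1) + 0.5
        status = rng.integers(0, 2, n)
        status[0] = 1
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)])
        tab = toy_table(times, status, X[:, 0])
        tab["z"] = X[:, 1]
        structure = one_stratum_structure(("x", "z"))
        Xd, _ = design_matrix(tab, structure)
        strata = _split_strata(tab, structure, Xd)
        for b1 in (-1.0, -0.3, 0.0, 0.7, 1.5):
            for b2 in (-0.5, 0.0, 1.0):
                beta = np.array([b1, b2])
                ll, _, _ = _loglik_parts(strata, beta, "breslow")
                assert ll == pytest.approx(brute_force_loglik(times, status, X, beta), abs=1e-10)

    def test_three_subject_analytic_optimum(self):
        # events at t=1 (x=1), 2 (x=0), 3 (x=1): the score equation gives
        # beta-hat = -(1/2) ln 2
        tab = toy_table([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 0.0, 1.0])
        fitted = fit(tab, one_stratum_structure())
        assert fitted.beta[0] == pytest.approx(-0.5 * np.log(2.0), abs=1e-8)
        # and agrees with direct 1-d maximization of the brute-force PL
        res = minimize_scalar(
            lambda b: -brute_force_loglik([1, 2, 3], [1, 1, 1], [[1.0], [0.0], [1.0]], [b]),
            bounds=(-3, 3),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fitted.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_zero_effect_structure_gives_null_loglik(self, stacked434):
        structure = EffectStructure(effects=())
        fitted = fit(stacked434, structure)
        assert fitted.df == 0
        assert fitted.loglik == fitted.loglik_null
        assert fitted.aic == pytest.approx(-2 * fitted.loglik_null)

    def test_matches_lifelines_on_single_stratum(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(0, 1, n)
        t = rng.exponential(10 * np.exp(-0.7 * x - 0.3 * z))
        status = (t < rng.uniform(2, 25, n)).astype(int)
        tab = toy_table(t, status, x)
        tab["z"] = z
        ours = fit(tab, one_stratum_structure(("x", "z")), ties="efron")
        cph = CoxPHFitter()
        cph.fit(
            pd.DataFrame({"t": t, "e": status, "x": x, "z": z}),
            duration_col="t",
            event_col="e",
        )
        np.testing.assert_allclose(ours.beta, cph.params_[["x", "z"]], atol=1e-5)
        np.testing.assert_allclose(
            ours.se, cph.standard_errors_[["x", "z"]], atol=1e-5
        )

    def test_score_vanishes_at_optimum(self, fitted_full, stacked434):
        X, _ = design_matrix(stacked434, fitted_full.structure)
        strata = _split_strata(stacked434, fitted_full.structure, X)
        _, grad, _ = _loglik_parts(strata, fitted_full.beta, "breslow")
        assert np.max(np.abs(grad)) < 1e-8

    def test_breslow_equals_efron_without_ties(self, stacked434):
        b = fit(stacked434, full_structure(), ties="breslow")
        e = fit(stacked434, full_structure(), ties="efron")
        np.testing.assert_allclose(b.beta, e.beta, atol=1e-7)
        assert b.loglik == pytest.approx(e.loglik, abs=1e-7)

    def test_centering_age_leaves_hr_loglik_aic_unchanged(self, stacked434, fitted_full):
        shifted = stacked434.copy()
        shifted["age"] = shifted["age"] - 60.0
        refit = fit(shifted, full_structure())
        np.testing.assert_allclose(refit.hazard_ratios, fitted_full.hazard_ratios, rtol=1e-8)
        assert refit.loglik == pytest.approx(fitted_full.loglik, abs=1e-6)
        assert refit.aic == pytest.approx(fitted_full.aic, abs=1e-6)

    def test_joint_stratified_fit_equals_per_transition_fits(self, stacked434, fitted_full):
        total_ll = 0.0
        betas = {}
        for trans in ("01", "02", "12"):
            sub = stacked434[stacked434["transition"] == trans].reset_index(drop=True)
            covs = ("age", "residual_tumor", "figo_high") + (("t010",) if trans == "12" else ())
            structure = EffectStructure(
                effects=tuple(Effect(c, frozenset({trans})) for c in covs),
                baseline_strata=ONE_STRATUM,
            )
            f = fit(sub, structure)
            total_ll += f.loglik
            betas.update(dict(zip(f.names, f.beta)))
        assert total_ll == pytest.approx(fitted_full.loglik, abs=1e-6)
        for name, joint in zip(fitted_full.names, fitted_full.beta):
            assert betas[name] == pytest.approx(joint, abs=1e-6)

    def test_monotone_likelihood_raises_with_coefficient_name(self):
        # the covariate perfectly orders events before censorings
        tab = toy_table([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0])
        with pytest.raises(cox_engine.ConvergenceError, match="x.01"):
            fit(tab, one_stratum_structure())

    def test_empty_stratum_raises(self, stacked434):
        no12 = stacked434[stacked434["transition"] != "12"]
        with pytest.raises(CoxError, match="12"):
            fit(no12, full_structure())


class TestBaseline:
    def test_null_model_baseline_is_nelson_aalen(self):
        tab = toy_table([1.0, 2.0, 3.0], [1, 1, 1], [0.0, 0.0, 0.0])
        fitted = fit(tab, EffectStructure(effects=(), baseline_strata=ONE_STRATUM))
        bh = fitted.baselines["01+02+12"]
        np.testing.assert_allclose(bh.times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(bh.increments, [1 / 3, 1 / 2, 1.0])

    def test_cumulative_baseline_nondecreasing(self, fitted_full):
        for bh in fitted_full.baselines.values():
            assert (bh.increments >= 0).all()
            cum = np.cumsum(bh.increments)
            assert (np.diff(cum) >= 0).all()

    def test_breslow_increment_formula_by_hand(self):
        # increment at u = d / sum(risk set exp(x beta)), risk sets shrink
        # as {1,2,3}, {2,3}, {3}
        tab = toy_table([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 0.0, 1.0])
        fitted = fit(tab, one_stratum_structure())
        eb = np.exp(fitted.beta[0])
        bh = fitted.baselines["01+02+12"]
        np.testing.assert_allclose(
            bh.increments, [1 / (2 * eb + 1), 1 / (1 + eb), 1 / eb], rtol=1e-10
        )


class TestLRTest:
    def test_identical_models_give_zero_statistic(self, fitted_full):
        stat, df, p = lr_test(fitted_full, fitted_full)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 0
        assert p == 1.0

    def test_chi_square_quantile(self):
        # frozen chi-square check: stat 3.841 on 1 df sits at p ~ 0.050
        from scipy import stats as sps

        assert sps.chi2.sf(3.841, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_non_nested_structures_rejected(self, stacked434):
        a = fit(stacked434, full_structure(covariates=("age",)))
        b = fit(stacked434, full_structure(covariates=("figo_high",)))
        with pytest.raises(CoxError, match="nested"):
            lr_test(a, b)

    def test_dropping_informative_covariate_is_detected(self, stacked434, fitted_full):
        nested = fit(stacked434, full_structure().drop("figo_high", {"01"}))
        stat, df, p = lr_test(nested, fitted_full)
        assert df == 1
        assert stat > 0
        assert p < 0.001


class TestSchoenfeld:
    def test_type_one_error_near_nominal_under_proportionality(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 100
        for _ in range(reps):
            rec = generate(paper_like_config(500), rng)
            tab = msdata.prepare(rec)
            fitted = fit(tab, full_structure())
            _, p = schoenfeld_ph_test(fitted, tab, "residual_tumor.01")
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_detects_strong_time_interaction(self):
        # x=1 has a steeply increasing hazard, x=0 a constant one: the
        # hazard ratio crosses over time, which the test must flag
        rng = np.random.default_rng(1)
        detected = 0
        for _ in range(10):
            n = 500
            x = np.repeat([0.0, 1.0], n // 2)
            t = np.where(x == 0, rng.exponential(1.0, n), rng.weibull(4.0, n) * 1.1)
            tab = toy_table(t, np.ones(n, int), x)
            fitted = fit(tab, one_stratum_structure())
            _, p = schoenfeld_ph_test(fitted, tab, "x.01")
            detected += p < 0.01
        assert detected >= 9

    def test_unknown_coefficient_rejected(self, fitted_full, stacked434):
        with pytest.raises(CoxError, match="nope"):
            schoenfeld_ph_test(fitted_full, stacked434, "nope")


class TestLogLogCurves:
    def test_single_jump_point(self):
        bh = StepHazard(np.array([2.0]), np.array([0.5]))
        fitted = fit(
            toy_table([1.0, 2.0], [1, 1], [0.0, 0.0]),
            EffectStructure(effects=(), baseline_strata=ONE_STRATUM),
        )
        fitted.baselines = {"01+02+12": bh}
        pts = loglog_curves(fitted)["01+02+12"]
        np.testing.assert_allclose(pts, [[np.log(2.0), np.log(0.5)]])

    def test_proportional_baselines_are_vertically_offset(self):
        t = np.linspace(1, 20, 15)
        inc = np.full_like(t, 0.05)
        k = 3.0
        a = StepHazard(t, inc)
        b = StepHazard(t, k * inc)
        fitted = fit(
            toy_table([1.0, 2.0], [1, 1], [0.0, 0.0]),
            EffectStructure(effects=(), baseline_strata=ONE_STRATUM),
        )
        fitted.baselines = {"a": a, "b": b}
        curves = loglog_curves(fitted)
        np.testing.assert_allclose(
            curves["b"][:, 1] - curves["a"][:, 1], np.log(k), atol=1e-12
        )

    def test_weibull_baseline_slope_equals_shape(self):
        # ln(cumhaz) = shape * ln t - shape * ln scale for a Weibull baseline
        shape, scale = 1.7, 12.0
        t = np.linspace(0.5, 40, 200)
        cum = (t / scale) ** shape
        inc = np.diff(np.concatenate([[0.0], cum]))
        fitted = fit(
            toy_table([1.0, 2.0], [1, 1], [0.0, 0.0]),
            EffectStructure(effects=(), baseline_strata=ONE_STRATUM),
        )
        fitted.baselines = {"w": StepHazard(t, inc)}
        pts = loglog_curves(fitted)["w"]
        slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        assert slope == pytest.approx(shape, rel=1e-6)


def test_model_json_round_trip(tmp_path, fitted_full):
    path = tmp_path / "model.json"
    fitted_full.to_json(path)
    back = cox_engine.FittedModel.from_json(path)
    np.testing.assert_allclose(back.beta, fitted_full.beta)
    np.testing.assert_allclose(back.vcov, fitted_full.vcov)
    assert back.names == fitted_full.names
    assert back.aic == pytest.approx(fitted_full.aic)
    for k, bh in fitted_full.baselines.items():
        np.testing.assert_allclose(back.baselines[k].times, bh.times)
        np.testing.assert_allclose(back.baselines[k].increments, bh.increments)


def test_vcov_symmetric_positive_semidefinite(fitted_full):
    v = fitted_full.vcov
    np.testing.assert_allclose(v, v.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(v) > -1e-12)
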