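"""Random-intercept logistic regression: limits, oracle, LRT identities."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from polcrab.glmm import (
    ConvergenceError,
    DegenerateGroupsWarning,
    GlmmResult,
    RandomInterceptLogit,
    fit_glmm,
    lrt,
    polarity_split_fits,
    effect_lrt,
)
from polcrab.synthdata import simulate_glmm_trials
from polcrab.validation import glmm_quadrature_check


def _result(effects, loglik, n_obs=100):
    coeffs = {"intercept": 0.0, **{e: 0.0 for e in effects}}
    return GlmmResult(coeffs, 0.5, loglik, n_obs, 10, True, tuple(effects))


class TestZeroVarianceLimit:
    def test_matches_plain_logistic(self):
        """When the variance estimate hits the boundary the GLMM is a plain logit.

        The fixture (true crab_sd = 0) is one where the ML random-intercept SD
        collapses to zero, so the mixed fit must coincide with an ordinary
        logistic regression.
        """
        import statsmodels.api as sm

        trials = simulate_glmm_trials(
            n_crabs=30, beta_contrast=3.0, beta_order=-0.05, crab_sd=0.0, seed=1
        )
        res = fit_glmm(trials, ("contrast", "order"))
        X = np.column_stack(
            [
                np.ones(len(trials)),
                [t.contrast for t in trials],
                [float(t.order) for t in trials],
            ]
        )
        y = np.array([1.0 if t.behaviours else 0.0 for t in trials])
        plain = sm.Logit(y, X).fit(disp=0)
        assert res.coefficients["contrast"] == pytest.approx(plain.params[1], abs=1e-3)
        assert res.coefficients["order"] == pytest.approx(plain.params[2], abs=1e-3)
        assert res.loglik == pytest.approx(plain.llf, abs=1e-3)
        assert res.random_intercept_sd < 0.05


def test_agrees_with_reference_mixed_model_implementation():
    """Cross-implementation check against R lme4 on a fixed simulated dataset.

    Reference values frozen from ``glmer(y ~ contrast + order + (1|crab_id),
    family=binomial, nAGQ=20)`` run on the identical generated trial table.
    """
    trials = simulate_glmm_trials(
        n_crabs=30, beta_contrast=3.0, beta_order=-0.05, crab_sd=0.0, seed=11
    )
    res = fit_glmm(trials, ("contrast", "order"))
    assert res.coefficients["intercept"] == pytest.approx(-0.578127465, abs=1e-3)
    assert res.coefficients["contrast"] == pytest.approx(2.702078220, abs=1e-3)
    assert res.coefficients["order"] == pytest.approx(0.006608396, abs=1e-3)
    assert res.random_intercept_sd == pytest.approx(0.380762, abs=1e-3)
    assert res.loglik == pytest.approx(-160.2678, abs=1e-3)


def test_marginal_loglik_matches_brute_force_quadrature():
    """AGQ vs scipy.integrate.quad on a 2-group toy dataset."""
    check = glmm_quadrature_check(seed=0)
    assert check["abs_diff"] < 1e-4


class TestLrt:
    def test_identical_models(self):
        full = _result(["contrast", "order"], -50.0)
        res = lrt(full, _result(["order"], -50.0))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_quantile_identity(self):
        full = _result(["contrast", "order"], -50.0)
        reduced = _result(["order"], -50.0 - 3.841 / 2)
        res = lrt(full, reduced)
        assert res.df == 1
        assert res.p == pytest.approx(0.05, abs=1e-3)
        assert res.p == pytest.approx(chi2_dist.sf(3.841, 1))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(_result(["contrast"], -50.0), _result(["order"], -51.0))

    def test_different_n_obs_rejected(self):
        with pytest.raises(ValueError):
            lrt(_result(["contrast", "order"], -50.0), _result(["order"], -51.0, n_obs=99))

    def test_negative_chi2_raises_convergence_error(self):
        with pytest.raises(ConvergenceError):
            lrt(_result(["contrast", "order"], -52.0), _result(["order"], -50.0))


class TestTrialInterface:
    def test_effect_detection_end_to_end(self):
        trials = simulate_glmm_trials(n_crabs=25, beta_contrast=4.0, crab_sd=0.5, seed=5)
        full, reduced, res = effect_lrt(trials, "contrast")
        assert full.n_groups == 25
        assert res.df == 1
        assert res.p < 0.01
        assert full.coefficients["contrast"] > 0

    def test_quadratic_term_available(self):
        trials = simulate_glmm_trials(n_crabs=15, beta_contrast=2.0, crab_sd=0.3, seed=6)
        res = fit_glmm(trials, ("contrast", "contrast2", "order"))
        assert set(res.coefficients) == {"intercept", "contrast", "contrast2", "order"}

    def test_single_group_falls_back_to_plain_logistic(self):
        trials = simulate_glmm_trials(n_crabs=1, beta_contrast=2.0, crab_sd=0.0, seed=7)
        with pytest.warns(DegenerateGroupsWarning):
            res = fit_glmm(trials, ("contrast",))
        assert res.random_intercept_sd == 0.0
        assert res.n_groups == 1


class TestPolaritySplits:
    def test_partition_accounting(self):
        trials = simulate_glmm_trials(n_crabs=10, beta_contrast=3.0, crab_sd=0.3, seed=8)
        pos = [t for t in trials if t.contrast >= 0]
        neg = [t for t in trials if t.contrast <= 0]
        controls = [t for t in trials if t.contrast == 0]
        assert len(pos) + len(neg) - len(controls) == len(trials)

    def test_symmetric_curve_gives_matching_magnitudes(self):
        # symmetric response in |contrast|: logit depends on |c| via +/- slopes
        rng = np.random.default_rng(9)
        from polcrab.behaviour import TrialRecord
        from polcrab.stimulus import generate_series
        from scipy.special import expit

        trials = []
        for i in range(40):
            b = rng.normal(0, 0.3)
            series = generate_series(np.linspace(-0.5, 0.5, 9), "polarization", int(rng.integers(2**31)))
            for order, e in enumerate(series.entries, 1):
                p = expit(-1.5 + 6.0 * abs(e.contrast) + b)
                trials.append(
                    TrialRecord(
                        f"crab{i}", "C_rugosus", "polarization", e.contrast, order,
                        [("retreat", 1.0)] if rng.uniform() < p else [],
                    )
                )
        splits = polarity_split_fits(trials)
        cpos = splits["positive"]["glmm"].coefficients["contrast"]
        cneg = splits["negative"]["glmm"].coefficients["contrast"]
        assert cpos > 0 and cneg < 0
        assert abs(cpos) == pytest.approx(abs(cneg), rel=0.5)
        assert splits["positive"]["lrt"].p < 0.05
        assert splits["negative"]["lrt"].p < 0.05

    def test_constant_response_flagged(self):
        from polcrab.behaviour import TrialRecord

        trials = [
            TrialRecord("a", "C_rugosus", "polarization", c, o, [("stop", 1.0)])
            for o, c in enumerate([-0.5, -0.25, 0.0, 0.25, 0.5], 1)
        ] + [
            TrialRecord("b", "C_rugosus", "polarization", c, o, [("stop", 1.0)])
            for o, c in enumerate([-0.5, -0.25, 0.0, 0.25, 0.5], 1)
        ]
        splits = polarity_split_fits(trials)
        assert splits["positive"]["non_identifiable"]
        assert splits["negative"]["non_identifiable"]


class TestRandomInterceptEstimator:
    def test_sklearn_params_roundtrip(self):
        est = RandomInterceptLogit(n_quad=12)
        assert est.get_params()["n_quad"] == 12
        est.set_params(n_quad=8)
        assert est.n_quad == 8

    def test_predict_proba_typical_animal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 1))
        groups = np.repeat(np.arange(6), 10)
        y = (rng.uniform(size=60) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(float)
        est = RandomInterceptLogit().fit(X, y, groups)
        proba = est.predict_proba(np.array([[-3.0], [3.0]]))
        assert proba[0, 1] < 0.5 < proba[1, 1]
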