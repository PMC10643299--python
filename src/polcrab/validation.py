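"""Closed-loop validation studies run against the synthetic generators.

Each study wires a ground-truth generator to the corresponding analysis stage
and measures how well the truth is recovered: Stokes round-trip error through
ADC quantization, psychometric-threshold recovery and bootstrap-interval
coverage, LRT type-I error and power for the random-intercept logistic model,
habituation-slope recovery, and agreement of the adaptive Gauss-Hermite
marginal likelihood with brute-force numerical integration.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from . import behaviour as bhv
from . import glmm
from .polarimetry import compute_stokes, demosaic, dop_aop, MASK_VALID
from .synthdata import (
    DEFAULT_CONTRAST_SET,
    ObserverModel,
    make_disc_scene,
    render_mosaic,
    simulate_glmm_trials,
    simulate_trials,
)


def _wrapped_angle_diff(a, b):
    return np.abs((a - b + 90.0) % 180.0 - 90.0)


def polarimetry_roundtrip_study(
    n_scenes: int = 100,
    grid: int = 16,
    bit_depth: int = 12,
    s0: float = 4000.0,
    dop_range=(0.05, 1.0),
    seed: int = 0,
) -> dict:
    """Render -> demosaic -> Stokes -> DoP/AoP recovery error, noiseless.

    Scenes are centred discs with background/disc DoP drawn from ``dop_range``
    and a random polarization angle; intensity sits near full scale (the
    exposure a polarimetrist would choose).  DoP below the range floor is
    excluded because AoP is ill-conditioned as DoP -> 0.  Returns the maximum
    absolute DoP and AoP errors over all valid pixels of all scenes.
    """
    rng = np.random.default_rng(seed)
    max_dop_err = 0.0
    max_aop_err = 0.0
    for _ in range(n_scenes):
        bg, disc = rng.uniform(*dop_range, size=2)
        aop = rng.uniform(-90.0, 90.0)
        scene = make_disc_scene(bg, disc, disc_radius_px=grid // 3, grid_size=grid, s0=s0, aop=aop)
        mosaic = render_mosaic(scene, bit_depth=bit_depth, noise_sd=0.0)
        maps = dop_aop(compute_stokes(*demosaic(mosaic)), mosaic)
        valid = maps.mask == MASK_VALID
        max_dop_err = max(max_dop_err, float(np.abs(maps.dop - scene.dop)[valid].max()))
        max_aop_err = max(
            max_aop_err, float(_wrapped_angle_diff(maps.aop, scene.aop)[valid].max())
        )
    return {
        "n_scenes": n_scenes,
        "max_dop_error": max_dop_err,
        "max_aop_error_deg": max_aop_err,
        "dop_tolerance": 2.0 / 2**bit_depth,
    }


def psychometric_recovery_study(
    n_reps: int = 500,
    n_crabs: int = 20,
    n_boot: int = 199,
    x50_true: float = 0.2,
    slope_true: float = 10.0,
    levels=None,
    seed: int = 0,
) -> dict:
    """Threshold recovery and bootstrap-interval coverage for the sigmoid fit.

    Each replicate draws one binary response per crab per contrast from a
    known 4PL (bottom 0, top 1), fits per-contrast proportions, and builds a
    95% percentile bootstrap interval for x50 by resampling crabs.  Reports
    the median recovered x50 and the fraction of intervals covering truth.
    """
    if levels is None:
        levels = np.linspace(0.0, 0.5, 9)
    levels = np.asarray(levels, dtype=float)
    p_true = bhv.four_param_logistic(levels, 0.0, 1.0, x50_true, slope_true)
    rng = np.random.default_rng(seed)

    def fit_x50(props, ns):
        est = bhv.PsychometricSigmoid().fit(levels, props, sample_weight=ns)
        return est.x50_

    x50s = np.empty(n_reps)
    covered = np.zeros(n_reps, dtype=bool)
    ns = np.full(levels.size, n_crabs, dtype=float)
    for r in range(n_reps):
        responses = rng.uniform(size=(n_crabs, levels.size)) < p_true  # crab x level
        x50s[r] = fit_x50(responses.mean(axis=0), ns)
        boot = np.empty(n_boot)
        idx = rng.integers(0, n_crabs, size=(n_boot, n_crabs))
        for b in range(n_boot):
            boot[b] = fit_x50(responses[idx[b]].mean(axis=0), ns)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        covered[r] = lo <= x50_true <= hi
    return {
        "n_reps": n_reps,
        "x50_true": x50_true,
        "median_x50": float(np.median(x50s)),
        "median_abs_error": float(np.median(np.abs(x50s - x50_true))),
        "coverage": float(covered.mean()),
    }


def lrt_calibration_study(
    n_null: int = 1000,
    n_power: int = 300,
    n_crabs: int = 20,
    crab_sd: float = 0.5,
    effect_size: float = 4.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error and power of the contrast LRT under the GLMM data model.

    Null replicates have no contrast effect (order effect and crab variance
    present); power replicates use the configured logit-scale contrast slope.
    """
    rng = np.random.default_rng(seed)

    def rejection_rate(n_reps, beta_contrast, intercept):
        rej = 0
        for _ in range(n_reps):
            trials = simulate_glmm_trials(
                n_crabs=n_crabs,
                intercept=intercept,
                beta_contrast=beta_contrast,
                beta_order=-0.05,
                crab_sd=crab_sd,
                seed=int(rng.integers(2**31)),
            )
            _, _, res = glmm.effect_lrt(trials, "contrast")
            rej += res.p < alpha
        return rej / n_reps

    return {
        "n_null": n_null,
        "n_power": n_power,
        "null_rejection_rate": rejection_rate(n_null, 0.0, -0.5),
        "power": rejection_rate(n_power, effect_size, -1.0),
        "alpha": alpha,
        "effect_size": effect_size,
    }


def habituation_recovery_study(
    n_reps: int = 500,
    n_crabs: int = 20,
    decrement: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of a known per-trial response decrement by the line fit.

    Uses a responsive observer (floor 0.55) over a 5-level series so the
    additive decrement never clamps probabilities at 0, which would bias the
    slope; the estimand is the probability change per trial, the same scale
    the line fit estimates.
    """
    rng = np.random.default_rng(seed)
    contrast_set = tuple(np.linspace(-0.5, 0.5, 5))
    hs = np.empty(n_reps)
    for r in range(n_reps):
        model = ObserverModel(
            bottom=0.55,
            top=0.95,
            slope=8.0,
            crab_sd=0.3,
            habituation_decrement=decrement,
            seed=int(rng.integers(2**31)),
        )
        trials = simulate_trials(model, n_crabs=n_crabs, contrast_set=contrast_set)
        orders = [t.order for t in trials]
        responses = [float(bhv.score_response(t)) for t in trials]
        hs[r] = bhv.fit_habituation(orders, responses).h
    return {
        "n_reps": n_reps,
        "true_h": -decrement,
        "mean_h": float(hs.mean()),
        "sd_h": float(hs.std()),
    }


def glmm_quadrature_check(seed: int = 0, n_quad: int = 20) -> dict:
    """AGQ marginal log-likelihood vs brute-force numerical integration.

    Builds a 2-group toy dataset and compares the adaptive Gauss-Hermite
    approximation with scipy.integrate.quad applied group by group, at
    parameter values away from the optimum.
    """
    rng = np.random.default_rng(seed)
    n_per = 6
    X = np.column_stack([np.ones(2 * n_per), rng.normal(size=2 * n_per)])
    gidx = np.repeat([0, 1], n_per)
    beta = np.array([-0.3, 1.2])
    sd = 0.7
    p = expit(X @ beta + np.array([0.4, -0.6])[gidx])
    y = (rng.uniform(size=2 * n_per) < p).astype(float)

    agq = glmm.marginal_loglik(X, y, gidx, 2, beta, sd, n_quad=n_quad)

    brute = 0.0
    for g in range(2):
        m = gidx == g
        eta0 = X[m] @ beta
        yg = y[m]

        def integrand(b):
            eta = eta0 + b
            ll = np.sum(yg * eta - np.logaddexp(0.0, eta))
            return np.exp(ll) * norm.pdf(b, scale=sd)

        val, _ = quad(integrand, -10 * sd, 10 * sd, limit=200, epsabs=1e-13, epsrel=1e-12)
        brute += np.log(val)
    return {
        "agq_loglik": float(agq),
        "quad_loglik": float(brute),
        "abs_diff": float(abs(agq - brute)),
    }
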