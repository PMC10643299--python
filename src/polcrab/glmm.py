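"""Random-intercept binary logistic regression and likelihood-ratio tests.

The repeated-measures structure of the looming assay (each crab sees a whole
contrast series) is handled with a generalized linear mixed model: a logistic
regression with a Gaussian random intercept per animal,

    y_ij | b_i ~ Bernoulli(logit^-1(x_ij' beta + b_i)),   b_i ~ N(0, sigma^2).

The marginal likelihood integrates the random intercept out of each group; we
maximise it with adaptive Gauss-Hermite quadrature (nodes recentred and
rescaled at each group's posterior mode, 20 nodes by default).  Fixed effects
(stimulus contrast, presentation order, optionally a squared centred contrast)
are tested by likelihood-ratio tests against the nested model with the effect
removed: chi2 = 2 * (ll_full - ll_reduced) on df = parameter difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .behaviour import TrialRecord, score_response

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """A likelihood comparison is inconsistent with nested optimisation."""


class DegenerateGroupsWarning(UserWarning):
    """Fewer than 2 groups: the random intercept is not identifiable."""


@dataclass
class GlmmResult:
    """Fitted random-intercept logistic regression."""

    coefficients: dict  # effect name -> estimate on the logit scale
    random_intercept_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    fixed_effects: tuple = ()


class LrtResult(NamedTuple):
    chi2: float
    df: int
    p: float


def _group_modes(offset, y, gidx, n_groups, inv_var, max_iter=50, tol=1e-10):
    """Newton solve for each group's posterior mode of the random intercept."""
    b = np.zeros(n_groups)
    h = np.full(n_groups, -inv_var)
    for _ in range(max_iter):
        eta = offset + b[gidx]
        p = expit(eta)
        grad = np.bincount(gidx, weights=y - p, minlength=n_groups) - b * inv_var
        h = -np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) - inv_var
        step = grad / h
        b -= step
        if np.max(np.abs(step)) < tol:
            break
    return b, h


def marginal_loglik(X, y, group_index, n_groups, beta, sd, n_quad=20):
    """Marginal log-likelihood of the random-intercept logistic model.

    Adaptive Gauss-Hermite approximation of
    ``sum_i log int prod_j Bernoulli(y_ij | expit(x_ij'beta + b)) N(b; 0, sd^2) db``
    with quadrature recentred at each group's posterior mode.
    """
    z, w = hermgauss(n_quad)
    offset = X @ beta
    inv_var = 1.0 / sd**2
    bhat, h = _group_modes(offset, y, group_index, n_groups, inv_var)
    scale = 1.0 / np.sqrt(-h)
    nodes = bhat[:, None] + np.sqrt(2.0) * scale[:, None] * z[None, :]  # (G, K)

    eta = offset[:, None] + nodes[group_index]  # (n, K)
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    ll_group = np.empty((n_groups, n_quad))
    for k in range(n_quad):
        ll_group[:, k] = np.bincount(group_index, weights=ll_obs[:, k], minlength=n_groups)
    ll_group += -0.5 * nodes**2 * inv_var - _LOG_SQRT_2PI - np.log(sd)

    log_int = (
        logsumexp(ll_group + np.log(w)[None, :] + z[None, :] ** 2, axis=1)
        + np.log(np.sqrt(2.0) * scale)
    )
    return float(log_int.sum())


class RandomInterceptLogit(BaseEstimator):
    """Maximum-likelihood logistic regression with a per-group Gaussian intercept.

    Parameters
    ----------
    n_quad : int
        Number of adaptive Gauss-Hermite nodes for the marginal likelihood.
    start_sd : float
        Starting value for the random-intercept SD.
    fit_intercept : bool
        Prepend a fixed intercept column to the design.

    Fitted attributes: ``intercept_``, ``coef_``, ``re_sd_``, ``loglik_``,
    ``n_obs_``, ``n_groups_``, ``converged_``.  With a single group the
    random intercept is unidentifiable; a plain logistic regression is fitted
    instead (``re_sd_ = 0``) with a :class:`DegenerateGroupsWarning`.
    """

    _LOG_SD_BOUNDS = (np.log(1e-6), np.log(50.0))

    def __init__(self, n_quad=20, start_sd=0.5, fit_intercept=True):
        self.n_quad = n_quad
        self.start_sd = start_sd
        self.fit_intercept = fit_intercept

    def _design(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.size > X.shape[1]:
            X = X.T
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, groups):
        Xd = self._design(X)
        y = np.asarray(y, dtype=float).reshape(-1)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary (0/1)")
        _, gidx = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = int(gidx.max()) + 1
        self.n_obs_, self.n_groups_ = len(y), n_groups
        if n_groups > len(y):
            raise ValueError("more groups than observations")

        beta0 = self._plain_logistic_start(Xd, y)
        if n_groups < 2:
            warnings.warn(
                "only one group: fitting a plain logistic regression, re_sd_ = 0",
                DegenerateGroupsWarning,
            )
            self._store(beta0, 0.0, _plain_loglik(Xd, y, beta0), converged=True)
            return self

        def nll(params):
            beta, log_sd = params[:-1], params[-1]
            return -marginal_loglik(Xd, y, gidx, n_groups, beta, np.exp(log_sd), self.n_quad)

        x0 = np.append(beta0, np.log(self.start_sd))
        bounds = [(None, None)] * Xd.shape[1] + [self._LOG_SD_BOUNDS]
        # optimizer slack between two nested fits is ~1e-6 in loglik units,
        # well inside the LRT negativity tolerance
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        self._store(res.x[:-1], float(np.exp(res.x[-1])), -float(res.fun), bool(res.success))
        return self

    @staticmethod
    def _plain_logistic_start(Xd, y):
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return np.asarray(sm.Logit(y, Xd).fit(disp=0, maxiter=100).params)
            except Exception:
                return np.zeros(Xd.shape[1])

    def _store(self, beta, sd, loglik, converged):
        beta = np.asarray(beta, dtype=float)
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.re_sd_ = float(sd)
        self.loglik_ = float(loglik)
        self.converged_ = converged

    def predict_proba(self, X):
        """Response probability for a typical animal (random intercept 0)."""
        eta = self._design(X) @ np.concatenate(
            [[self.intercept_], self.coef_] if self.fit_intercept else [self.coef_]
        )
        p = expit(eta)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _plain_loglik(Xd, y, beta):
    eta = Xd @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# Trial-level interface

KNOWN_EFFECTS = ("contrast", "contrast2", "order")


def _design_from_trials(trials, fixed_effects, window):
    kept = [t for t in trials if not t.excluded]
    y = np.array([float(score_response(t, window)) for t in kept])
    groups = np.array([t.crab_id for t in kept])
    contrast = np.array([t.contrast for t in kept])
    order = np.array([float(t.order) for t in kept])
    centred = contrast - contrast.mean()
    columns = {"contrast": contrast, "contrast2": centred**2, "order": order}
    for eff in fixed_effects:
        if eff not in KNOWN_EFFECTS:
            raise ValueError(f"unknown fixed effect {eff!r}; expected one of {KNOWN_EFFECTS}")
    X = np.column_stack([columns[e] for e in fixed_effects]) if fixed_effects else np.empty((len(y), 0))
    return X, y, groups


def fit_glmm(
    trials,
    fixed_effects=("contrast", "order"),
    window=None,
    n_quad=20,
) -> GlmmResult:
    """Random-intercept logistic regression on scored trials.

    ``fixed_effects`` is a subset of ``("contrast", "contrast2", "order")``;
    ``contrast2`` is the squared centred contrast (the curvature control used
    when residuals show an irregular pattern).  Grouping is by crab.
    """
    fixed_effects = tuple(fixed_effects)
    X, y, groups = _design_from_trials(trials, fixed_effects, window)
    est = RandomInterceptLogit(n_quad=n_quad).fit(X, y, groups)
    coefficients = {"intercept": est.intercept_}
    coefficients.update({e: float(c) for e, c in zip(fixed_effects, est.coef_)})
    return GlmmResult(
        coefficients=coefficients,
        random_intercept_sd=est.re_sd_,
        loglik=est.loglik_,
        n_obs=est.n_obs_,
        n_groups=est.n_groups_,
        converged=est.converged_,
        fixed_effects=fixed_effects,
    )


def lrt(full: GlmmResult, reduced: GlmmResult, tol: float = 1e-4) -> LrtResult:
    """Likelihood-ratio test of the nested ``reduced`` model against ``full``."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    if not set(reduced.fixed_effects) < set(full.fixed_effects):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.fixed_effects) - len(reduced.fixed_effects)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol:
        raise ConvergenceError(
            f"full-model log-likelihood below reduced model (chi2 = {stat:.3g}); "
            "one of the fits did not converge"
        )
    stat = max(stat, 0.0)
    return LrtResult(chi2=float(stat), df=df, p=float(chi2_dist.sf(stat, df)))


def effect_lrt(trials, effect, fixed_effects=("contrast", "order"), window=None, n_quad=20):
    """Fit full and effect-removed models and LRT the named effect.

    Returns (full GlmmResult, reduced GlmmResult, LrtResult).
    """
    fixed_effects = tuple(fixed_effects)
    if effect not in fixed_effects:
        raise ValueError(f"effect {effect!r} not among fixed effects {fixed_effects}")
    reduced_effects = tuple(e for e in fixed_effects if e != effect)
    full = fit_glmm(trials, fixed_effects, window, n_quad)
    reduced = fit_glmm(trials, reduced_effects, window, n_quad)
    return full, reduced, lrt(full, reduced)


def polarity_split_fits(trials, window=None, n_quad=20):
    """Separate contrast-effect models for positive and negative contrasts.

    Zero-contrast control trials anchor both subsets.  Each split fits
    contrast + order and LRTs the contrast effect; a split with constant
    response (or a missing polarity) is flagged non-identifiable instead of
    fitted.
    """
    out = {}
    for label, keep in (
        ("positive", lambda c: c >= 0),
        ("negative", lambda c: c <= 0),
    ):
        subset = [t for t in trials if not t.excluded and keep(t.contrast)]
        nonzero = [t for t in subset if t.contrast != 0]
        if not nonzero:
            warnings.warn(f"no {label}-contrast trials; returning partial result")
            out[label] = {"glmm": None, "lrt": None, "non_identifiable": True}
            continue
        responses = {score_response(t, window) for t in subset}
        if len(responses) < 2:
            out[label] = {"glmm": None, "lrt": None, "non_identifiable": True}
            continue
        full, reduced, result = effect_lrt(subset, "contrast", ("contrast", "order"), window, n_quad)
        out[label] = {"glmm": full, "reduced": reduced, "lrt": result, "non_identifiable": False}
    return out
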