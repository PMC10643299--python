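"""Behavioural trial scoring and contrast-response / habituation models.

Trials are single looming presentations scored for three defensive behaviours
(*stop*, *retreat*, *walk*); a trial counts as a response if any behaviour
starts inside the scoring window.  Contrast-response curves are fitted with a
four-parameter logistic (base-10 slope, matching the convention of the usual
Matlab ``sigm_fit`` routine)

    p(x) = bottom + (top - bottom) / (1 + 10**((x50 - x) * slope))

whose ``x50`` is the half-maximum detection threshold, and habituation is the
slope of an ordinary least-squares line through mean response probability per
presentation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

BEHAVIOUR_KINDS = ("stop", "retreat", "walk")

#: Default scoring windows (s from loom onset): expansion + hold.
RESPONSE_WINDOWS = {"terrestrial": (0.0, 5.0), "marine": (0.0, 12.0)}

TERRESTRIAL_SPECIES = ("C_rugosus", "C_brevimanus")
MARINE_SPECIES = ("P_bernhardus",)


class InsufficientDataError(ValueError):
    """Too few distinct levels to fit the requested model."""


class ExcludedTrialError(ValueError):
    """Operation applied to an excluded trial."""


@dataclass
class TrialRecord:
    """One stimulus presentation to one crab."""

    crab_id: str
    species: str
    modality: str
    contrast: float
    order: int
    behaviours: list = field(default_factory=list)  # (kind, onset_s) pairs
    pre_stimulus_full_retreat: bool = False
    excluded: bool = False

    def __post_init__(self):
        if self.order < 1:
            raise ValueError(f"presentation order must be >= 1, got {self.order}")
        for kind, onset in self.behaviours:
            if kind not in BEHAVIOUR_KINDS:
                raise ValueError(f"unknown behaviour kind {kind!r}")
            if not np.isfinite(onset):
                raise ValueError("behaviour onset must be finite")


@dataclass
class PsychometricFit:
    bottom: float
    top: float
    x50: float
    slope: float
    converged: bool


@dataclass
class HabituationFit:
    h: float  # change in response probability per trial
    intercept: float


def default_window(species: str) -> tuple[float, float]:
    habitat = "marine" if species in MARINE_SPECIES else "terrestrial"
    return RESPONSE_WINDOWS[habitat]


def score_response(trial: TrialRecord, window: tuple[float, float] | None = None) -> bool:
    """True iff any behaviour onset falls inside the scoring window."""
    if trial.excluded:
        raise ExcludedTrialError(
            "trial is excluded; run apply_exclusions and score only the kept trials"
        )
    if window is None:
        window = default_window(trial.species)
    t0, t1 = window
    return any(t0 <= onset <= t1 for _, onset in trial.behaviours)


def apply_exclusions(trials):
    """Split trials into (kept, excluded) by the pre-stimulus full-retreat rule.

    A trial is excluded when the animal fully retreated into its shell before
    loom onset (a state unrelated to the stimulus).  Idempotent; marks the
    ``excluded`` flag on the excluded records.
    """
    kept, excluded = [], []
    for t in trials:
        if t.pre_stimulus_full_retreat:
            t.excluded = True
            excluded.append(t)
        else:
            kept.append(t)
    return kept, excluded


def four_param_logistic(x, bottom, top, x50, slope):
    """4PL psychometric function with base-10 slope."""
    with np.errstate(over="ignore"):  # extreme slopes saturate cleanly
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((x50 - np.asarray(x, float)) * slope))


class PsychometricSigmoid(RegressorMixin, BaseEstimator):
    """Four-parameter logistic contrast-response curve.

    Least-squares fit of the 4PL to per-contrast response proportions,
    optionally weighted by trial counts.  Fitted attributes follow the
    scikit-learn convention: ``bottom_``, ``top_``, ``x50_``, ``slope_``,
    ``converged_``.  ``converged_`` is False when the optimizer fails, the
    curve is essentially flat, or ``x50_`` escapes the fitted contrast range.

    Parameters
    ----------
    slope_bound : float
        Symmetric bound on the base-10 slope.
    x50_margin : float
        How far (as a fraction of the contrast span) x50 may move outside the
        data range during optimization.
    flat_slope_tol : float
        |slope| below which the curve is declared degenerate.
    """

    def __init__(self, slope_bound=1e3, x50_margin=0.5, flat_slope_tol=1e-3, max_nfev=400):
        self.slope_bound = slope_bound
        self.x50_margin = x50_margin
        self.flat_slope_tol = flat_slope_tol
        self.max_nfev = max_nfev

    @staticmethod
    def _residual_jac(params, x, y, sw):
        b, t, m, s = params
        with np.errstate(over="ignore"):
            u = 10.0 ** np.clip((m - x) * s, -300.0, 300.0)
            denom = 1.0 + u
            f = b + (t - b) / denom
            r = (f - y) * sw
            ln10 = np.log(10.0)
            # u/denom^2 written as (u/denom)/denom so saturated pixels give 0
            sat = (u / denom) / denom
            jac = np.column_stack(
                [
                    (u / denom) * sw,
                    (1.0 / denom) * sw,
                    (-(t - b) * ln10 * s * sat) * sw,
                    (-(t - b) * ln10 * (m - x) * sat) * sw,
                ]
            )
        return r, jac

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 4:
            raise InsufficientDataError(
                "sigmoid fit needs >= 4 distinct contrast levels (4 free parameters)"
            )
        sw = np.ones_like(y) if sample_weight is None else np.sqrt(
            np.asarray(sample_weight, dtype=float)
        )

        xmin, xmax = x.min(), x.max()
        span = xmax - xmin
        lo = [0.0, 0.0, xmin - self.x50_margin * span, -self.slope_bound]
        hi = [1.0, 1.0, xmax + self.x50_margin * span, self.slope_bound]

        order = np.argsort(x)
        ys = y[order]
        y0, y1 = ys[: max(1, len(ys) // 3)].mean(), ys[-max(1, len(ys) // 3):].mean()
        mid = (y.min() + y.max()) / 2.0
        crossings = np.nonzero(np.diff(np.sign(ys - mid)))[0]
        x50_0 = x[order][crossings[0]] if crossings.size else (xmin + xmax) / 2.0
        slope_0 = np.sign(y1 - y0) * 4.0 / span if y1 != y0 else 1.0 / span
        p0 = np.clip(
            [min(y0, y1), max(y0, y1), x50_0, slope_0],
            np.asarray(lo) + 1e-9,
            np.asarray(hi) - 1e-9,
        )

        res = least_squares(
            lambda p: self._residual_jac(p, x, y, sw)[0],
            p0,
            jac=lambda p: self._residual_jac(p, x, y, sw)[1],
            bounds=(lo, hi),
            max_nfev=self.max_nfev,
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        b, t, m, s = res.x
        if b > t:  # the 4PL is invariant under (b,t,s) -> (t,b,-s)
            b, t, s = t, b, -s
        self.bottom_, self.top_, self.x50_, self.slope_ = float(b), float(t), float(m), float(s)
        self.converged_ = bool(
            res.success
            and abs(s) > self.flat_slope_tol
            and (t - b) > self.flat_slope_tol  # flat curve: x50 meaningless
            and xmin <= m <= xmax
        )
        self.x_range_ = (float(xmin), float(xmax))
        return self

    def predict(self, X):
        return four_param_logistic(X, self.bottom_, self.top_, self.x50_, self.slope_)

    def result(self) -> PsychometricFit:
        return PsychometricFit(self.bottom_, self.top_, self.x50_, self.slope_, self.converged_)


class HabituationLine(RegressorMixin, BaseEstimator):
    """Response probability as a straight line in presentation order.

    Averages the binary responses at each order, then fits an ordinary
    least-squares line through the per-order means; ``slope_`` is the
    habituation rate h (change in response probability per trial).
    """

    def fit(self, X, y):
        orders = np.asarray(X, dtype=float).reshape(-1)
        responses = np.asarray(y, dtype=float).reshape(-1)
        if orders.shape != responses.shape:
            raise ValueError("X and y must have the same length")
        levels = np.unique(orders)
        if levels.size < 2:
            raise InsufficientDataError("habituation fit needs >= 2 distinct order values")
        means = np.array([responses[orders == o].mean() for o in levels])
        slope, intercept = np.polyfit(levels, means, 1)
        self.slope_, self.intercept_ = float(slope), float(intercept)
        self.order_levels_, self.order_means_ = levels, means
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float)

    def result(self) -> HabituationFit:
        return HabituationFit(h=self.slope_, intercept=self.intercept_)


def fit_sigmoid(contrasts, proportions, n_trials=None, **params) -> PsychometricFit:
    """Fit the 4PL contrast-response curve to per-contrast proportions.

    ``n_trials`` (per contrast) weights the residuals; the half-maximum
    threshold is the fitted ``x50``.
    """
    est = PsychometricSigmoid(**params).fit(contrasts, proportions, sample_weight=n_trials)
    return est.result()


def fit_habituation(orders, responses) -> HabituationFit:
    """Habituation rate h: slope of response probability over stimulus order."""
    return HabituationLine().fit(orders, responses).result()


def response_table(trials, window=None):
    """Per-contrast (level, proportion, n) summary of scored responses."""
    kept = [t for t in trials if not t.excluded]
    contrasts = np.array([t.contrast for t in kept])
    scores = np.array([score_response(t, window) for t in kept], dtype=float)
    levels = np.unique(contrasts)
    props = np.array([scores[contrasts == c].mean() for c in levels])
    ns = np.array([(contrasts == c).sum() for c in levels])
    return levels, props, ns
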