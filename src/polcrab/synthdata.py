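"""Ground-truth-known synthetic inputs for every pipeline stage.

Two generators mirror the study's two data kinds:

* Stokes scenes (uniform background with a centred disc of differing DoP,
  horizontally polarized) rendered into DoFP camera mosaics through the
  Malus-law forward model ``I_phi = 0.5*(S0 + S1 cos 2phi + S2 sin 2phi)``
  with optional Gaussian read noise and ADC quantization; and

* behavioural trial tables drawn from a psychometric observer population with
  a polarity-asymmetric contrast-response curve, a per-crab random intercept
  on the logit scale, and an additive per-trial habituation decrement on the
  probability scale (matching how the habituation rate h is defined).

Defaults reproduce the study conditions: a 50%-polarized horizontal
background, DoP contrasts spanning -0.5 to +0.5, one randomized series per
crab, and a detection threshold (x50 = 0.2) inside the species' reported
threshold band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .behaviour import TrialRecord, four_param_logistic
from .polarimetry import DEFAULT_LAYOUT, DimensionError, RawMosaic, _validate_layout
from .stimulus import generate_series

#: Nine DoP contrasts against the 0.5-polarized background (stimulus DoP 0..1).
DEFAULT_CONTRAST_SET = tuple(np.round(np.linspace(-0.5, 0.5, 9), 4))
DEFAULT_BACKGROUND_DOP = 0.5


@dataclass
class StokesScene:
    """Ground-truth polarization scene: S0 (counts), DoP and AoP (degrees) fields."""

    S0: np.ndarray
    dop: np.ndarray
    aop: np.ndarray

    def __post_init__(self):
        self.S0 = np.asarray(self.S0, dtype=float)
        self.dop = np.asarray(self.dop, dtype=float)
        self.aop = np.asarray(self.aop, dtype=float)
        if not (self.S0.shape == self.dop.shape == self.aop.shape):
            raise DimensionError("S0, dop, aop must share one shape")
        if np.any((self.dop < 0) | (self.dop > 1)):
            raise ValueError("dop must lie in [0, 1]")
        if np.any(self.S0 < 0):
            raise ValueError("S0 must be non-negative")

    @property
    def S1(self):
        return self.S0 * self.dop * np.cos(2 * np.radians(self.aop))

    @property
    def S2(self):
        return self.S0 * self.dop * np.sin(2 * np.radians(self.aop))


@dataclass
class ObserverModel:
    """Psychometric observer population generating binary loom responses.

    The response probability at contrast c is an asymmetric 4PL: threshold
    ``x50_pos`` governs positive contrasts and ``x50_neg`` negative ones
    (response grows with |c| on each side).  Per-crab intercepts shift the
    probability on the logit scale (SD ``crab_sd``); habituation subtracts
    ``habituation_decrement`` per presentation on the probability scale.
    """

    bottom: float = 0.05
    top: float = 0.95
    x50_pos: float = 0.2
    x50_neg: float = -0.2
    slope: float = 10.0
    crab_sd: float = 0.5
    habituation_decrement: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.bottom <= self.top <= 1:
            raise ValueError("need 0 <= bottom <= top <= 1")
        if self.crab_sd < 0:
            raise ValueError("crab_sd must be non-negative")

    def probability(self, contrast):
        """Population-level response probability before crab and order effects."""
        c = np.asarray(contrast, dtype=float)
        p_pos = four_param_logistic(c, self.bottom, self.top, self.x50_pos, self.slope)
        p_neg = four_param_logistic(-c, self.bottom, self.top, -self.x50_neg, self.slope)
        return np.where(c >= 0, p_pos, p_neg)


def make_disc_scene(
    background_dop: float,
    disc_dop: float,
    disc_radius_px: int,
    grid_size,
    s0: float = 4000.0,
    aop: float = 0.0,
) -> StokesScene:
    """Uniform scene with a centred disc of differing DoP.

    ``grid_size`` is the superpixel grid (int or (rows, cols)); intensity is
    uniform at ``s0`` counts and the polarization plane is ``aop`` degrees
    everywhere (0° = horizontal, the study's background).
    """
    for d in (background_dop, disc_dop):
        if not 0 <= d <= 1:
            raise ValueError("dop values must lie in [0, 1]")
    shape = (grid_size, grid_size) if np.isscalar(grid_size) else tuple(grid_size)
    if 2 * disc_radius_px > min(shape):
        raise DimensionError(
            f"disc of radius {disc_radius_px} px does not fit a {shape} grid"
        )
    rr, cc = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= disc_radius_px**2
    dop = np.where(inside, disc_dop, background_dop)
    return StokesScene(
        S0=np.full(shape, float(s0)),
        dop=dop,
        aop=np.full(shape, float(aop)),
    )


def render_mosaic(
    scene: StokesScene,
    layout=DEFAULT_LAYOUT,
    bit_depth: int = 12,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RawMosaic:
    """Render a scene into a DoFP mosaic via the Malus-law forward model.

    Each scene pixel becomes one 2x2 superpixel; subpixel intensities are
    ``0.5*(S0 + S1 cos 2phi + S2 sin 2phi)`` plus Gaussian read noise, rounded
    and clipped to the ADC range.  Deterministic given ``seed``.
    """
    lay = _validate_layout(layout)
    S0, S1, S2 = scene.S0, scene.S1, scene.S2
    h, w = S0.shape
    mosaic = np.empty((2 * h, 2 * w), dtype=float)
    for dr in range(2):
        for dc in range(2):
            phi = np.radians(float(lay[dr, dc]))
            mosaic[dr::2, dc::2] = 0.5 * (S0 + S1 * np.cos(2 * phi) + S2 * np.sin(2 * phi))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mosaic += rng.normal(0.0, noise_sd, mosaic.shape)
    full_scale = 2**bit_depth - 1
    quantized = np.clip(np.round(mosaic), 0, full_scale).astype(np.uint16)
    return RawMosaic(pixels=quantized, bit_depth=bit_depth, layout=tuple(map(tuple, lay.tolist())))


def simulate_trials(
    model: ObserverModel,
    n_crabs: int,
    contrast_set=DEFAULT_CONTRAST_SET,
    n_series_per_crab: int = 1,
    modality: str = "polarization",
    species: str = "C_rugosus",
):
    """Draw a synthetic behavioural trial table from the observer model.

    Each crab receives ``n_series_per_crab`` independently randomized series
    over ``contrast_set`` (each contrast once per series); presentation order
    runs across the concatenated series.  Per trial,
    ``p = clip(expit(logit(p_base(c)) + b_crab) - d*(order-1), 0, 1)`` and the
    response is Bernoulli(p); responders get a single nominal *retreat* onset
    at 1 s.  Deterministic given ``model.seed``.
    """
    if n_crabs < 1:
        raise ValueError("need at least one crab")
    contrast_set = list(contrast_set)
    if not contrast_set:
        raise ValueError("contrast set must be non-empty")
    rng = np.random.default_rng(model.seed)
    trials = []
    eps = 1e-12
    for i in range(n_crabs):
        crab_id = f"crab{i:03d}"
        offset = rng.normal(0.0, model.crab_sd) if model.crab_sd > 0 else 0.0
        order = 0
        for _ in range(n_series_per_crab):
            series = generate_series(contrast_set, modality, seed=int(rng.integers(2**31)))
            for entry in series.entries:
                order += 1
                p_base = float(model.probability(entry.contrast))
                p = float(expit(logit(np.clip(p_base, eps, 1 - eps)) + offset))
                p = np.clip(p - model.habituation_decrement * (order - 1), 0.0, 1.0)
                responded = rng.uniform() < p
                trials.append(
                    TrialRecord(
                        crab_id=crab_id,
                        species=species,
                        modality=modality,
                        contrast=entry.contrast,
                        order=order,
                        behaviours=[("retreat", 1.0)] if responded else [],
                    )
                )
    return trials


def simulate_glmm_trials(
    n_crabs: int = 20,
    contrast_set=DEFAULT_CONTRAST_SET,
    intercept: float = -0.5,
    beta_contrast: float = 0.0,
    beta_order: float = -0.05,
    crab_sd: float = 0.5,
    seed: int = 0,
    modality: str = "polarization",
    species: str = "C_rugosus",
):
    """Trial table drawn directly from the logistic-GLMM data model.

    ``logit p = intercept + beta_contrast*c + beta_order*order + b_crab`` with
    ``b_crab ~ N(0, crab_sd^2)``; contrasts are shuffled per crab so contrast
    and presentation order are not confounded.  Used for LRT calibration and
    power studies where the generating model must be the fitted one.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_crabs):
        crab_id = f"crab{i:03d}"
        b = rng.normal(0.0, crab_sd) if crab_sd > 0 else 0.0
        series = generate_series(contrast_set, modality, seed=int(rng.integers(2**31)))
        for order, entry in enumerate(series.entries, start=1):
            eta = intercept + beta_contrast * entry.contrast + beta_order * order + b
            responded = rng.uniform() < expit(eta)
            trials.append(
                TrialRecord(
                    crab_id=crab_id,
                    species=species,
                    modality=modality,
                    contrast=entry.contrast,
                    order=order,
                    behaviours=[("retreat", 1.0)] if responded else [],
                )
            )
    return trials
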