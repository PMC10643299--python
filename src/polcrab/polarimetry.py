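"""Division-of-focal-plane (DoFP) polarimetry.

A DoFP polarization camera tiles its sensor with 2x2 "superpixels" whose four
subpixels sit behind wire-grid micro-polarizers at 0°, 45°, 90° and 135°.  From
the four subpixel intensities of each superpixel the linear Stokes parameters

    S0 = (I0 + I45 + I90 + I135) / 2
    S1 = I0 - I90
    S2 = I45 - I135

are formed, and from them the degree of linear polarization (DoP) and angle of
polarization (AoP):

    DoP = sqrt(S1^2 + S2^2) / S0        in [0, 1]
    AoP = 0.5 * atan2(S2, S1)           degrees, 0° = horizontal, [-90, 90)

The half-sum convention for S0 makes an ideal polarizer's 50% transmission of
unpolarized light cancel, so S0 equals the scene intensity under the forward
model I_phi = 0.5 * (S0 + S1*cos(2*phi) + S2*sin(2*phi)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Superpixel arrangement of the Sony IMX250MZR-family sensors: row-major
#: [[90, 45], [135, 0]].  Overridable everywhere a layout is accepted.
DEFAULT_LAYOUT: tuple[tuple[int, int], tuple[int, int]] = ((90, 45), (135, 0))

POLARIZER_ANGLES = (0, 45, 90, 135)

# Exposure-mask labels.
MASK_VALID = 0
MASK_OVEREXPOSED = 1
MASK_UNDEREXPOSED = 2

#: Below this DoP the angle of polarization is numerically meaningless; such
#: pixels report AoP 0° and should be excluded from AoP summaries.
AOP_UNDEFINED_DOP = 0.01


class DimensionError(ValueError):
    """Image dimensions incompatible with the 2x2 superpixel structure."""


class LayoutError(ValueError):
    """Superpixel layout does not contain each polarizer angle exactly once."""


def _validate_layout(layout) -> np.ndarray:
    arr = np.asarray(layout)
    if arr.shape != (2, 2):
        raise LayoutError(f"layout must be 2x2, got shape {arr.shape}")
    if sorted(arr.ravel().tolist()) != sorted(POLARIZER_ANGLES):
        raise LayoutError(
            f"layout must contain each of {POLARIZER_ANGLES} exactly once, got {arr.tolist()}"
        )
    return arr


@dataclass
class RawMosaic:
    """Single-channel polarizer-mosaicked camera frame.

    Parameters
    ----------
    pixels : ndarray
        2-D array of digital numbers in ``[0, 2**bit_depth - 1]``; both
        dimensions must be even.
    bit_depth : int
        Bits per pixel of the sensor ADC (8 or 12 for common DoFP cameras).
    layout : 2x2 nested sequence
        Polarizer angle (degrees) of each subpixel position within a
        superpixel, row-major.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    layout: tuple = DEFAULT_LAYOUT

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError("mosaic must be a 2-D array")
        h, w = self.pixels.shape
        if h % 2 or w % 2:
            raise DimensionError(f"mosaic dimensions must be even, got {h}x{w}")
        _validate_layout(self.layout)
        full_scale = 2**self.bit_depth - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > full_scale):
            raise ValueError(
                f"pixel values outside [0, {full_scale}] for bit depth {self.bit_depth}"
            )

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class StokesImage:
    """Per-superpixel linear Stokes parameters (S0, S1, S2), in counts."""

    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray

    def __post_init__(self):
        self.S0 = np.asarray(self.S0, dtype=float)
        self.S1 = np.asarray(self.S1, dtype=float)
        self.S2 = np.asarray(self.S2, dtype=float)
        if not (self.S0.shape == self.S1.shape == self.S2.shape):
            raise DimensionError("S0, S1, S2 must share one shape")


@dataclass
class PolarizationMaps:
    """DoP/AoP/intensity maps with a per-superpixel exposure mask.

    ``mask`` holds :data:`MASK_VALID`, :data:`MASK_OVEREXPOSED` or
    :data:`MASK_UNDEREXPOSED`; ``n_clipped`` counts pixels whose noisy DoP
    exceeded 1 before clipping.
    """

    dop: np.ndarray
    aop: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    n_clipped: int = 0


def demosaic(mosaic: RawMosaic):
    """Split a mosaic into four co-registered polarizer-channel images.

    Returns
    -------
    (I0, I45, I90, I135) : tuple of ndarray
        One image per polarizer angle, each half the mosaic's dimensions.
        Superpixels are non-overlapping 2x2 blocks; output pixel ``(r, c)``
        is the subpixel of superpixel ``(r, c)`` carrying that angle.
    """
    layout = _validate_layout(mosaic.layout)
    px = mosaic.pixels
    channels = {}
    for dr in range(2):
        for dc in range(2):
            channels[int(layout[dr, dc])] = px[dr::2, dc::2]
    return tuple(channels[a] for a in POLARIZER_ANGLES)


def compute_stokes(I0, I45, I90, I135) -> StokesImage:
    """Linear Stokes parameters from the four polarizer-channel images."""
    arrays = [np.asarray(a, dtype=float) for a in (I0, I45, I90, I135)]
    if len({a.shape for a in arrays}) != 1:
        raise DimensionError("the four channel images must share one shape")
    I0, I45, I90, I135 = arrays
    return StokesImage(
        S0=(I0 + I45 + I90 + I135) / 2.0,
        S1=I0 - I90,
        S2=I45 - I135,
    )


def _wrap_aop(deg: np.ndarray) -> np.ndarray:
    """Wrap polarization angles into the half-open interval [-90, 90)."""
    return (deg + 90.0) % 180.0 - 90.0


def dop_aop(
    stokes: StokesImage,
    mosaic: RawMosaic | None = None,
    saturation_margin: int = 0,
    floor_threshold: float = 1.0,
) -> PolarizationMaps:
    """Degree and angle of polarization with exposure masking.

    A superpixel is marked overexposed when any of its four subpixels reaches
    ``full_scale - saturation_margin`` (requires ``mosaic``), and underexposed
    when ``S0 <= floor_threshold``.  DoP is clipped to [0, 1] (noise can push
    sqrt(S1^2+S2^2) above S0); the clip count is recorded and logged.  AoP is
    reported as 0° where it is undefined (DoP < :data:`AOP_UNDEFINED_DOP` or
    S0 at the floor); such pixels should be excluded from AoP statistics.
    """
    S0, S1, S2 = stokes.S0, stokes.S1, stokes.S2
    lit = S0 > floor_threshold

    with np.errstate(divide="ignore", invalid="ignore"):
        dop = np.where(lit, np.hypot(S1, S2) / np.where(lit, S0, 1.0), 0.0)
    n_clipped = int(np.count_nonzero(dop > 1.0))
    if n_clipped:
        logger.info("dop_aop: clipped %d pixels with DoP > 1 (noise)", n_clipped)
    dop = np.clip(dop, 0.0, 1.0)

    aop = _wrap_aop(np.degrees(0.5 * np.arctan2(S2, S1)))
    aop = np.where(lit & (dop >= AOP_UNDEFINED_DOP), aop, 0.0)

    mask = np.full(S0.shape, MASK_VALID, dtype=np.uint8)
    if mosaic is not None:
        sat = mosaic.pixels >= (mosaic.full_scale - saturation_margin)
        h, w = sat.shape
        sat_super = sat.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))
        if sat_super.shape != S0.shape:
            raise DimensionError("mosaic does not match the Stokes image shape")
        mask[sat_super] = MASK_OVEREXPOSED
    mask[~lit & (mask == MASK_VALID)] = MASK_UNDEREXPOSED

    return PolarizationMaps(dop=dop, aop=aop, intensity=S0, mask=mask, n_clipped=n_clipped)


def render_false_colour(maps: PolarizationMaps, channel: str) -> np.ndarray:
    """False-colour 8-bit rendering of one polarization map.

    ``dop`` maps [0, 1] onto a sequential colormap (viridis), ``aop`` maps
    [-90, 90) onto a cyclic colormap (twilight) so -90° and +90° meet, and
    ``intensity`` is greyscale.  Overexposed superpixels render white and
    underexposed ones black.

    Returns an ``(H, W, 3)`` uint8 array.
    """
    import matplotlib

    if channel == "dop":
        cmap = matplotlib.colormaps["viridis"]
        norm = np.clip(maps.dop, 0.0, 1.0)
    elif channel == "aop":
        cmap = matplotlib.colormaps["twilight"]
        norm = (maps.aop + 90.0) / 180.0
    elif channel == "intensity":
        cmap = matplotlib.colormaps["gray"]
        peak = maps.intensity.max()
        norm = maps.intensity / peak if peak > 0 else np.zeros_like(maps.intensity)
    else:
        raise ValueError(f"unknown channel {channel!r}; expected dop, aop or intensity")

    rgb = (cmap(norm)[..., :3] * 255).round().astype(np.uint8)
    rgb[maps.mask == MASK_OVEREXPOSED] = (255, 255, 255)
    rgb[maps.mask == MASK_UNDEREXPOSED] = (0, 0, 0)
    return rgb
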