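"""Expanding-disc looming stimuli in intensity or polarization contrast.

The looming assay animates a disc that grows from a small visual angle to its
full angular size (disc of diameter D viewed at distance d subtends
``2*arctan(D / 2d)``), holds at maximum size, then disappears.  Discs differ
from the background either in Weber contrast (radiance) or in DoP contrast
(degree-of-polarization difference), and a screen calibration maps grey levels
to the physical quantity actually displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Expansion/hold presets: terrestrial hermit crabs saw 3 s looms, the marine
#: species 10 s, both followed by a 2 s hold at full size.
EXPANSION_PRESETS = {
    "terrestrial": {"expand_duration": 3.0, "hold_duration": 2.0},
    "marine": {"expand_duration": 10.0, "hold_duration": 2.0},
}


class GamutError(ValueError):
    """Requested contrast is outside what the calibrated screen can show."""


@dataclass
class LoomSpec:
    """Geometry and timing of one expanding-disc stimulus."""

    disc_diameter: float = 12.0  # cm
    viewing_distance: float = 35.0  # cm
    expand_duration: float = 3.0  # s
    hold_duration: float = 2.0  # s
    theta_start: float = 0.5  # degrees; constant-approach cannot start at 0
    frame_rate: float = 60.0  # Hz
    profile: str = "constant_approach"  # or "exponential"

    def __post_init__(self):
        if self.disc_diameter <= 0 or self.viewing_distance <= 0:
            raise ValueError("disc_diameter and viewing_distance must be positive")
        if self.expand_duration <= 0:
            raise ValueError("expand_duration must be positive")
        if self.profile not in ("constant_approach", "exponential"):
            raise ValueError(f"unknown expansion profile {self.profile!r}")
        if not 0 <= self.theta_start < self.theta_max:
            raise ValueError("theta_start must lie in [0, maximum angle)")

    @property
    def theta_max(self) -> float:
        return angular_size(self.disc_diameter, self.viewing_distance)


@dataclass
class SeriesEntry:
    modality: str
    contrast: float
    interval_s: float


@dataclass
class StimulusSeries:
    """One randomized presentation series: each contrast exactly once."""

    entries: list[SeriesEntry]
    seed: int


def angular_size(diameter: float, distance: float) -> float:
    """Visual angle (degrees) subtended by a disc of ``diameter`` at ``distance``."""
    if distance <= 0:
        raise ValueError("viewing distance must be positive")
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return np.degrees(2.0 * np.arctan(diameter / (2.0 * distance)))


def expansion_profile(spec: LoomSpec) -> pd.DataFrame:
    """Frame-by-frame visual angle of the looming disc.

    ``constant_approach`` models a disc of radius R closing at constant speed
    v, reaching the screen-plane size at the end of expansion:
    ``theta(t) = 2*arctan(R / (v*(t_c - t)))`` with v and the virtual-collision
    time ``t_c = expand_duration + eps`` solved from ``theta(0) = theta_start``
    and ``theta(T) = theta_max``.  ``exponential`` grows the angle
    geometrically: ``theta(t) = theta_start * (theta_max/theta_start)**(t/T)``.
    During the hold the angle stays at ``theta_max``.

    Returns a DataFrame with columns ``frame``, ``time_s``, ``theta_deg``.
    """
    T = spec.expand_duration
    theta_max = spec.theta_max
    n_frames = int(round((T + spec.hold_duration) * spec.frame_rate)) + 1
    t = np.arange(n_frames) / spec.frame_rate
    expanding = t <= T

    if spec.profile == "constant_approach":
        if spec.theta_start <= 0:
            raise ValueError(
                "constant_approach cannot start from 0°: a finite-size disc at "
                "finite distance always subtends a positive angle; use a small "
                "theta_start or the exponential profile"
            )
        R = spec.disc_diameter / 2.0
        cot = lambda a_deg: 1.0 / np.tan(np.radians(a_deg) / 2.0)
        # v*t_c = R*cot(theta_start/2)   and   v*(t_c - T) = R*cot(theta_max/2)
        v = R * (cot(spec.theta_start) - cot(theta_max)) / T
        t_c = R * cot(spec.theta_start) / v
        theta = np.degrees(2.0 * np.arctan(R / (v * (t_c - np.minimum(t, T)))))
    else:
        theta0 = max(spec.theta_start, 1e-6 * theta_max)
        theta = theta0 * (theta_max / theta0) ** (np.minimum(t, T) / T)

    theta = np.where(expanding, theta, theta_max)
    theta[np.isclose(t, T) | (t > T)] = theta_max
    return pd.DataFrame({"frame": np.arange(n_frames), "time_s": t, "theta_deg": theta})


def weber_contrast(i_object: float, i_background: float):
    """Weber contrast ``(I_object - I_background) / I_background``."""
    i_background = np.asarray(i_background, dtype=float)
    if np.any(i_background <= 0):
        raise ValueError("background radiance must be positive")
    return (np.asarray(i_object, dtype=float) - i_background) / i_background


def dop_contrast(dop_stimulus: float, dop_background: float):
    """Signed DoP contrast: stimulus DoP minus background DoP."""
    s = np.asarray(dop_stimulus, dtype=float)
    b = np.asarray(dop_background, dtype=float)
    if np.any((s < 0) | (s > 1) | (b < 0) | (b > 1)):
        raise ValueError("degree of polarization must lie in [0, 1]")
    return s - b


class ScreenCalibration:
    """Grey-level calibration of the stimulus screen.

    Wraps two measured tables indexed by 8-bit grey level: radiance (relative
    units) and the degree of polarization produced against the polarization
    screen.  Lookup and inversion are piecewise linear; the radiance curve is
    regularised to be non-decreasing (cumulative maximum) before inversion.
    """

    def __init__(self, grey, radiance, dop=None):
        self.grey = np.asarray(grey, dtype=float)
        if np.any(np.diff(self.grey) <= 0):
            raise ValueError("grey levels must be strictly increasing")
        self.radiance = np.maximum.accumulate(np.asarray(radiance, dtype=float))
        if dop is not None:
            dop = np.asarray(dop, dtype=float)
            if np.any((dop < 0) | (dop > 1)):
                raise ValueError("calibrated DoP values must lie in [0, 1]")
            dop = np.maximum.accumulate(dop)
        self.dop = dop

    @classmethod
    def identity(cls, n_levels: int = 256) -> "ScreenCalibration":
        """Synthetic identity calibration: radiance = grey, DoP = grey/255."""
        grey = np.arange(n_levels, dtype=float)
        return cls(grey, grey, grey / (n_levels - 1))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenCalibration":
        dop = df["dop"].to_numpy() if "dop" in df.columns else None
        return cls(df["grey"].to_numpy(), df["radiance"].to_numpy(), dop)

    def radiance_of(self, grey):
        return np.interp(grey, self.grey, self.radiance)

    def dop_of(self, grey):
        if self.dop is None:
            raise ValueError("this calibration has no DoP table")
        return np.interp(grey, self.grey, self.dop)

    def _invert(self, table: np.ndarray, target: float, what: str) -> float:
        lo, hi = table[0], table[-1]
        if not lo <= target <= hi:
            raise GamutError(f"target {what} {target:g} outside achievable range [{lo:g}, {hi:g}]")
        return float(np.interp(target, table, self.grey))

    def grey_for_radiance(self, radiance: float) -> float:
        return self._invert(self.radiance, radiance, "radiance")

    def grey_for_dop(self, dop: float) -> float:
        if self.dop is None:
            raise ValueError("this calibration has no DoP table")
        return self._invert(self.dop, dop, "DoP")


def grey_for_target(
    calib: ScreenCalibration,
    modality: str,
    background_setting: float,
    target_contrast: float,
) -> float:
    """Foreground grey level producing ``target_contrast`` against the background.

    For ``intensity`` the background setting is a grey level and the target is
    a Weber contrast; for ``polarization`` the background setting is a DoP and
    the target is a DoP contrast.  Raises :class:`GamutError` (naming the
    achievable range) when the screen cannot produce the request.
    """
    if modality == "intensity":
        bg_rad = calib.radiance_of(background_setting)
        if bg_rad <= 0:
            raise ValueError("background radiance must be positive")
        return calib.grey_for_radiance(bg_rad * (1.0 + target_contrast))
    if modality == "polarization":
        return calib.grey_for_dop(background_setting + target_contrast)
    raise ValueError(f"unknown modality {modality!r}")


def generate_series(
    contrast_set,
    modality: str,
    seed: int,
    interval_range: tuple[float, float] = (60.0, 180.0),
) -> StimulusSeries:
    """Seeded random presentation series over one modality.

    Uniformly shuffles the contrast set (each contrast appears exactly once)
    and draws inter-trial intervals uniformly from ``interval_range`` (the
    1–3 min pacing of the assay).  Deterministic given ``seed``.
    """
    contrasts = list(contrast_set)
    if not contrasts:
        raise ValueError("contrast set must be non-empty")
    if modality not in ("intensity", "polarization"):
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(contrasts))
    intervals = rng.uniform(*interval_range, size=len(contrasts))
    entries = [
        SeriesEntry(modality=modality, contrast=float(contrasts[i]), interval_s=float(iv))
        for i, iv in zip(order, intervals)
    ]
    return StimulusSeries(entries=entries, seed=seed)
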