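"""Display geometry, angular units, and acuity-scaling arithmetic.

Everything downstream of the simulator is expressed in two unit systems:
degrees of visual angle measured from the point of regard, and screen
pixels with the origin at the top-left corner (x rightward, y downward).
This module owns the conversions between them, plus the logMAR letter-size
conventions used by the MNREAD-style scoring.

Conventions
-----------
* logMAR is log10 of the minimum angle of resolution (MAR) in arcminutes.
* Letter size follows the MNREAD x-height convention: the lowercase
  x-height subtends 5 * MAR arcminutes, so 0.0 logMAR corresponds to a
  5-arcmin x-height.
* The pixels-per-degree mapping is flat (small-angle approximation) with
  separate horizontal and vertical scales; over a 43 deg wide display the
  tangent correction this ignores is below 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DisplayModel",
    "LogMarSize",
    "deg_to_px",
    "px_to_deg",
    "logmar_to_xheight_deg",
    "logmar_to_xheight_arcmin",
    "distance_adjusted_logmar",
    "expected_acuity_gain",
]


@dataclass(frozen=True)
class DisplayModel:
    """Screen resolution and angular subtense at a reference viewing distance.

    Defaults describe a 1920 x 1080 display subtending 43 x 25 degrees of
    visual angle when viewed from 65 cm.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_deg: float = 43.0
    height_deg: float = 25.0
    reference_distance_cm: float = 65.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("display resolution must be positive")
        if not (self.width_deg > 0 and self.height_deg > 0):
            raise ValueError("display angular subtense must be positive")
        if not (self.reference_distance_cm > 0):
            raise ValueError("reference viewing distance must be positive")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_deg

    @property
    def px_per_deg_mean(self) -> float:
        """Mean of the horizontal and vertical scales; used for isotropic
        quantities such as Gaussian phosphene extents."""
        return 0.5 * (self.px_per_deg_x + self.px_per_deg_y)

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class LogMarSize:
    """A letter size on the logMAR scale (x-height = 5 * MAR arcmin)."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("logMAR size must be finite")

    @property
    def xheight_arcmin(self) -> float:
        return 5.0 * 10.0 ** self.value

    @property
    def xheight_deg(self) -> float:
        return self.xheight_arcmin / 60.0


def _as_logmar(size: "LogMarSize | float") -> float:
    v = size.value if isinstance(size, LogMarSize) else float(size)
    if not math.isfinite(v):
        raise ValueError("logMAR size must be finite")
    return v


def deg_to_px(angle_deg, display: DisplayModel, axis: str = "x"):
    """Convert degrees of visual angle to pixels along one screen axis.

    ``axis`` is ``"x"``, ``"y"``, or ``"mean"`` (isotropic scale).
    Accepts scalars or arrays; the mapping is linear through zero.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angle must be finite")
    scale = {
        "x": display.px_per_deg_x,
        "y": display.px_per_deg_y,
        "mean": display.px_per_deg_mean,
    }[axis]
    out = a * scale
    return float(out) if np.isscalar(angle_deg) or out.ndim == 0 else out


def px_to_deg(length_px, display: DisplayModel, axis: str = "x"):
    """Inverse of :func:`deg_to_px` along the same axis."""
    p = np.asarray(length_px, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("length must be finite")
    scale = {
        "x": display.px_per_deg_x,
        "y": display.px_per_deg_y,
        "mean": display.px_per_deg_mean,
    }[axis]
    out = p / scale
    return float(out) if np.isscalar(length_px) or out.ndim == 0 else out


def logmar_to_xheight_arcmin(size: "LogMarSize | float") -> float:
    """x-height in arcminutes for a logMAR size (5 * 10**logMAR)."""
    return 5.0 * 10.0 ** _as_logmar(size)


def logmar_to_xheight_deg(size: "LogMarSize | float") -> float:
    """x-height in degrees of visual angle for a logMAR size."""
    return logmar_to_xheight_arcmin(size) / 60.0


def distance_adjusted_logmar(
    nominal: "LogMarSize | float", actual_cm: float, reference_cm: float
) -> float:
    """Effective logMAR demand of a fixed-size stimulus viewed from
    ``actual_cm`` instead of the ``reference_cm`` it was sized for.

    Moving farther away shrinks the stimulus angularly, so the effective
    size (and hence the acuity demand) drops by log10 of the distance
    ratio: ``nominal - log10(actual / reference)``.
    """
    if not (actual_cm > 0 and reference_cm > 0):
        raise ValueError("viewing distances must be positive")
    return _as_logmar(nominal) - math.log10(actual_cm / reference_cm)


def expected_acuity_gain(count_hi: float, count_lo: float) -> float:
    """Expected logMAR acuity improvement from raising the phosphene count.

    Treating the phosphene array as a two-dimensional sampler, linear
    resolution scales with the square root of the count, so the expected
    logMAR gain for a count ratio ``count_hi / count_lo`` is
    ``0.5 * log10(count_hi / count_lo)`` (0.15 logMAR per doubling).
    """
    if count_hi <= 0 or count_lo <= 0:
        raise ValueError("phosphene counts must be positive")
    return 0.5 * math.log10(count_hi / count_lo)
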