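"""Second-order gaze-tracker correction from a 3-by-3 dot grid.

Raw tracker coordinates are mapped to screen-true coordinates by a full
bivariate quadratic per output axis (terms 1, x, y, x^2, y^2, xy) fitted
by least squares to repeated fixations on a 9-point calibration grid.
This absorbs gain, offset, and minor smooth distortions; with clean data
only the gain and offset terms are appreciably non-zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import DisplayModel

__all__ = [
    "CalibrationModel",
    "TERMS",
    "fit_correction",
    "apply_correction",
    "calibration_grid",
]

TERMS = ("1", "x", "y", "x^2", "y^2", "xy")


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), x, y, x * x, y * y, x * y]
    )


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis quadratic coefficients (order: 1, x, y, x^2, y^2, xy)."""

    coef_x: np.ndarray
    coef_y: np.ndarray
    residual_rms: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(TERMS),
                "coef_x": list(map(float, self.coef_x)),
                "coef_y": list(map(float, self.coef_y)),
                "residual_rms": self.residual_rms,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["coef_x"], dtype=float),
            np.asarray(d["coef_y"], dtype=float),
            float(d["residual_rms"]),
        )


def calibration_grid(
    display: DisplayModel | None = None, margin: float = 0.05
) -> np.ndarray:
    """The 9 target locations: a 3x3 grid spanning the screen with a
    fractional margin on each side.  Returns an array of (x, y) pixels."""
    display = display or DisplayModel()
    xs = np.linspace(margin * display.width_px, (1 - margin) * display.width_px, 3)
    ys = np.linspace(margin * display.height_px, (1 - margin) * display.height_px, 3)
    return np.array([(x, y) for y in ys for x in xs])


def fit_correction(raw_points: np.ndarray, true_points: np.ndarray) -> CalibrationModel:
    """Least-squares fit of the quadratic correction.

    ``raw_points`` and ``true_points`` are matching (n, 2) arrays; at
    least 6 non-degenerate pairs are required (the 9-point grid design
    provides 9-27).  Raises on rank-deficient designs, naming the
    degeneracy.
    """
    raw = np.asarray(raw_points, dtype=float)
    true = np.asarray(true_points, dtype=float)
    if raw.shape != true.shape or raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw and true points must be matching (n, 2) arrays")
    if raw.shape[0] < 6:
        raise ValueError("need at least 6 point pairs for the quadratic fit")
    A = _design(raw[:, 0], raw[:, 1])
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        raise ValueError(
            f"degenerate calibration design (rank {rank} < 6): the raw "
            "points do not span a full quadratic basis (e.g. collinear "
            "or coincident targets)"
        )
    coef_x, _, _, _ = np.linalg.lstsq(A, true[:, 0], rcond=None)
    coef_y, _, _, _ = np.linalg.lstsq(A, true[:, 1], rcond=None)
    pred = np.column_stack([A @ coef_x, A @ coef_y])
    rms = float(np.sqrt(np.mean(np.sum((pred - true) ** 2, axis=1))))
    return CalibrationModel(coef_x, coef_y, rms)


def apply_correction(model: CalibrationModel, raw) -> np.ndarray:
    """Evaluate the fitted polynomial at raw positions ((n, 2) or (2,))."""
    pts = np.atleast_2d(np.asarray(raw, dtype=float))
    A = _design(pts[:, 0], pts[:, 1])
    out = np.column_stack([A @ model.coef_x, A @ model.coef_y])
    return out[0] if np.asarray(raw).ndim == 1 else out
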