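"""Gaze-referenced phosphene patterns for a simulated thalamic prosthesis.

A pattern is a set of phosphenes given in gaze-relative degrees of visual
angle: each has a position (x, y) and a one-sigma Gaussian extent that
grows linearly with eccentricity,

    sigma = 0.043 * rho + 0.083   [deg],  rho = sqrt(x**2 + y**2).

Three density tiers (High / Medium / Low) correspond to devices with
1757, 1029, and 522 phosphenes in total, of which 381, 231, and 124 lie
within 10 deg of the point of regard.  Those four integers per tier are
enforced exactly by stratified sampling; everything else about the layout
follows a radially symmetric density profile that is calibrated against
published window counts for the High tier and shared (same shape, scaled
amplitude) by the other tiers.

The radial density is piecewise:

    d(rho) = amplitude * (1 + rho / rho0) ** -exponent          rho <= 10
    d(rho) = outer_amplitude * (1 + rho / outer_rho0) ** -q     rho  > 10

``amplitude`` is the density at the point of regard in phosphenes/deg^2.
The inner shape is fitted; the outer tail is a fixed inverse-square-like
falloff (q = 2), which mimics how receptive-field density declines with
the inverse magnification factor at larger eccentricities.  The published
window counts are mutually inconsistent with any single monotone radial
profile once the central/total split is enforced, so the two strata are
treated as separate shapes and the density steps at the 10 deg boundary;
see docs/methods.md for the calibration details.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "SIGMA_SLOPE",
    "SIGMA_INTERCEPT",
    "CENTRAL_RADIUS_DEG",
    "TIERS",
    "Tier",
    "Circle",
    "Rect",
    "Phosphene",
    "DensityProfile",
    "ProfileFit",
    "PhosphenePattern",
    "phosphene_sigma",
    "fit_density_profile",
    "calibrate_profile",
    "default_profile",
    "generate_pattern",
    "count_in_window",
    "perceptual_efficiency",
    "HIGH_WINDOW_CALIBRATION",
]

SIGMA_SLOPE = 0.043
SIGMA_INTERCEPT = 0.083
CENTRAL_RADIUS_DEG = 10.0


def phosphene_sigma(rho_deg):
    """One-sigma Gaussian extent (deg) of a phosphene at eccentricity rho."""
    r = np.asarray(rho_deg, dtype=float)
    if np.any(r < 0):
        raise ValueError("eccentricity must be non-negative")
    out = SIGMA_SLOPE * r + SIGMA_INTERCEPT
    return float(out) if np.isscalar(rho_deg) or out.ndim == 0 else out


@dataclass(frozen=True)
class Tier:
    name: str
    total: int
    central: int
    electrode_spacing_um: int  # metadata only


TIERS: dict[str, Tier] = {
    "high": Tier("high", 1757, 381, 375),
    "medium": Tier("medium", 1029, 231, 475),
    "low": Tier("low", 522, 124, 600),
}


@dataclass(frozen=True)
class Circle:
    """Circle of the given radius centered on the point of regard."""

    radius_deg: float


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle centered on the point of regard."""

    width_deg: float
    height_deg: float


@dataclass(frozen=True)
class Phosphene:
    x_deg: float
    y_deg: float
    sigma_deg: float


# Gauss-Legendre nodes reused for rectangle integrals.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(120)


@dataclass(frozen=True)
class DensityProfile:
    """Radially symmetric phosphene density, optionally with an outer tail.

    ``density(rho)`` is in phosphenes per square degree.  When the outer
    fields are ``None`` the single inner law extends to ``rho_max_deg``.
    """

    amplitude: float
    rho0: float
    exponent: float
    rho_max_deg: float = 45.0
    boundary_deg: float | None = None
    outer_amplitude: float | None = None
    outer_rho0: float | None = None
    outer_exponent: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.rho0 <= 0 or self.exponent < 0:
            raise ValueError("amplitude and rho0 must be positive, exponent >= 0")
        if self.boundary_deg is not None and not (
            0 < self.boundary_deg < self.rho_max_deg
        ):
            raise ValueError("stratum boundary must lie inside the field")

    def density(self, rho_deg):
        r = np.asarray(rho_deg, dtype=float)
        inner = self.amplitude * (1.0 + r / self.rho0) ** (-self.exponent)
        if self.boundary_deg is None:
            out = inner
        else:
            outer = self.outer_amplitude * (1.0 + r / self.outer_rho0) ** (
                -self.outer_exponent
            )
            out = np.where(r <= self.boundary_deg, inner, outer)
        out = np.where(r > self.rho_max_deg, 0.0, out)
        return float(out) if np.isscalar(rho_deg) or out.ndim == 0 else out

    # -- expected counts ------------------------------------------------
    def expected_count(self, region: "Circle | Rect") -> float:
        """Expected number of phosphenes in a centered region, from the
        area integral of the density."""
        if isinstance(region, Circle):
            r_hi = min(region.radius_deg, self.rho_max_deg)
            val, _ = integrate.quad(
                lambda r: 2.0 * math.pi * r * self.density(r), 0.0, r_hi, limit=200
            )
            return val
        if isinstance(region, Rect):
            hw = region.width_deg / 2.0
            hh = region.height_deg / 2.0
            x = 0.5 * hw * (_GL_NODES + 1.0)
            y = 0.5 * hh * (_GL_NODES + 1.0)
            X, Y = np.meshgrid(x, y, indexing="ij")
            D = self.density(np.hypot(X, Y))
            quadrant = (0.5 * hw) * (0.5 * hh) * np.einsum(
                "i,j,ij->", _GL_WEIGHTS, _GL_WEIGHTS, D
            )
            return 4.0 * quadrant
        raise TypeError(f"unknown region type: {region!r}")

    def to_dict(self) -> dict:
        d = {
            "amplitude": self.amplitude,
            "rho0": self.rho0,
            "exponent": self.exponent,
            "rho_max_deg": self.rho_max_deg,
        }
        if self.boundary_deg is not None:
            d.update(
                boundary_deg=self.boundary_deg,
                outer_amplitude=self.outer_amplitude,
                outer_rho0=self.outer_rho0,
                outer_exponent=self.outer_exponent,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DensityProfile":
        return cls(**d)


def _shape_circle_mass(rho0: float, p: float, r_lo: float, r_hi: float) -> float:
    """Integral of 2*pi*r*(1+r/rho0)**-p over [r_lo, r_hi]."""
    val, _ = integrate.quad(
        lambda r: 2.0 * math.pi * r * (1.0 + r / rho0) ** (-p),
        r_lo,
        r_hi,
        limit=200,
    )
    return val


def _shape_rect_mass(rho0: float, p: float, hw: float, hh: float) -> float:
    x = 0.5 * hw * (_GL_NODES + 1.0)
    y = 0.5 * hh * (_GL_NODES + 1.0)
    X, Y = np.meshgrid(x, y, indexing="ij")
    D = (1.0 + np.hypot(X, Y) / rho0) ** (-p)
    return 4.0 * (0.5 * hw) * (0.5 * hh) * np.einsum(
        "i,j,ij->", _GL_WEIGHTS, _GL_WEIGHTS, D
    )


@dataclass
class ProfileFit:
    """Diagnostics from :func:`fit_density_profile`."""

    profile: DensityProfile
    regions: list
    targets: np.ndarray
    expected: np.ndarray
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        self.flagged = bool(np.any(np.abs(self.relative_residuals) > 0.25))

    @property
    def relative_residuals(self) -> np.ndarray:
        return self.expected / self.targets - 1.0


# Published window counts for the High tier used as calibration
# constraints, alongside the tier totals (count, centered window).
HIGH_WINDOW_CALIBRATION: list[tuple[Circle | Rect, float]] = [
    (Rect(10.0, 3.5), 218.0),
    (Rect(10.0, 7.0), 352.0),
    (Rect(5.7, 5.7), 223.0),
    (Rect(1.7, 1.7), 45.0),
]


def fit_density_profile(
    constraints: Sequence[tuple["Circle | Rect", float]],
    rho_max_deg: float = 45.0,
    central: tuple[float, float, float] | None = None,
) -> ProfileFit:
    """Fit the radial density law to expected-count constraints.

    Parameters
    ----------
    constraints
        ``(region, target_count)`` pairs; regions are centered circles or
        rectangles in degrees.
    rho_max_deg
        Field extent.
    central
        ``(boundary_deg, central_count, total_count)``.  When given, the
        fit assumes the stratified construction used by
        :func:`generate_pattern`: exactly ``central_count`` phosphenes
        inside the boundary and ``total_count - central_count`` outside,
        so expected counts for regions inside the boundary are the inner
        shape conditioned to ``central_count``.  All window constraints
        must then lie inside the boundary.

    Returns
    -------
    ProfileFit
        Fitted profile plus per-constraint residual diagnostics; the fit
        is flagged when any residual exceeds 25% (the published counts
        are not exactly representable by a radially symmetric profile).
    """
    if not constraints:
        raise ValueError("at least one constraint is required")
    regions = [r for r, _ in constraints]
    targets = np.array([t for _, t in constraints], dtype=float)
    if np.any(targets <= 0):
        raise ValueError("target counts must be positive")

    if len(constraints) < 3:
        # Under-determined for the full family: fall back to the uniform
        # limit (exponent -> 0), where amplitude is count / area.
        region, target = constraints[0]
        if isinstance(region, Circle):
            area = math.pi * min(region.radius_deg, rho_max_deg) ** 2
        else:
            area = region.width_deg * region.height_deg
        prof = DensityProfile(target / area, 1.0, 0.0, rho_max_deg)
        return ProfileFit(prof, regions, targets, np.array([target]))

    if central is None:
        # Raw fit: amplitude, rho0, exponent against the area integrals.
        def resid(theta):
            amp, rho0, p = np.exp(theta)
            prof = DensityProfile(amp, rho0, p, rho_max_deg)
            return [
                math.log(prof.expected_count(r) / t)
                for r, t in zip(regions, targets)
            ]

        sol = optimize.least_squares(
            resid,
            np.log([1.0, 1.0, 2.0]),
            bounds=(np.log([1e-9, 1e-2, 1e-3]), np.log([1e6, 1e3, 1e4])),
        )
        amp, rho0, p = np.exp(sol.x)
        prof = DensityProfile(amp, rho0, p, rho_max_deg)
        expected = np.array([prof.expected_count(r) for r in regions])
        return ProfileFit(prof, regions, targets, expected)

    boundary, n_central, n_total = central
    for r in regions:
        corner = (
            r.radius_deg
            if isinstance(r, Circle)
            else math.hypot(r.width_deg / 2.0, r.height_deg / 2.0)
        )
        if corner > boundary:
            raise ValueError(
                "stratified fit requires window constraints inside the "
                f"central boundary ({boundary} deg); got {r!r}"
            )

    def cond_expected(rho0: float, p: float) -> np.ndarray:
        m_central = _shape_circle_mass(rho0, p, 0.0, boundary)
        vals = []
        for r in regions:
            if isinstance(r, Circle):
                m = _shape_circle_mass(rho0, p, 0.0, r.radius_deg)
            else:
                m = _shape_rect_mass(rho0, p, r.width_deg / 2.0, r.height_deg / 2.0)
            vals.append(n_central * m / m_central)
        return np.array(vals)

    def resid(theta):
        rho0, p = np.exp(theta)
        return np.log(cond_expected(rho0, p) / targets)

    sol = optimize.least_squares(
        resid,
        np.log([1.0, 2.0]),
        bounds=(np.log([1e-2, 1e-3]), np.log([1e3, 1e4])),
    )
    rho0, p = np.exp(sol.x)
    # Amplitude such that the inner stratum integrates to the exact
    # central count.
    amplitude = n_central / _shape_circle_mass(rho0, p, 0.0, boundary)
    # Fixed inverse-square-like outer tail carrying the remaining count.
    outer_rho0, outer_exponent = 1.0, 2.0
    outer_mass = integrate.quad(
        lambda r: 2.0 * math.pi * r * (1.0 + r / outer_rho0) ** (-outer_exponent),
        boundary,
        rho_max_deg,
        limit=200,
    )[0]
    prof = DensityProfile(
        amplitude,
        rho0,
        p,
        rho_max_deg,
        boundary_deg=boundary,
        outer_amplitude=(n_total - n_central) / outer_mass,
        outer_rho0=outer_rho0,
        outer_exponent=outer_exponent,
    )
    return ProfileFit(prof, regions, targets, cond_expected(rho0, p))


_DEFAULT_PROFILE_CACHE: dict[float, DensityProfile] = {}


def calibrate_profile(rho_max_deg: float = 45.0) -> ProfileFit:
    """Calibrate the High-tier profile against the published window counts."""
    high = TIERS["high"]
    return fit_density_profile(
        HIGH_WINDOW_CALIBRATION,
        rho_max_deg=rho_max_deg,
        central=(CENTRAL_RADIUS_DEG, high.central, high.total),
    )


def default_profile(rho_max_deg: float = 45.0) -> DensityProfile:
    """Cached calibrated profile shared by all tiers."""
    if rho_max_deg not in _DEFAULT_PROFILE_CACHE:
        _DEFAULT_PROFILE_CACHE[rho_max_deg] = calibrate_profile(rho_max_deg).profile
    return _DEFAULT_PROFILE_CACHE[rho_max_deg]


@dataclass(frozen=True)
class PhosphenePattern:
    """An ordered set of phosphenes plus the metadata that produced it."""

    tier: str
    seed: int
    rho_max_deg: float
    profile: DensityProfile
    x_deg: np.ndarray
    y_deg: np.ndarray
    sigma_deg: np.ndarray

    def __len__(self) -> int:
        return self.x_deg.size

    @property
    def eccentricity_deg(self) -> np.ndarray:
        return np.hypot(self.x_deg, self.y_deg)

    @property
    def phosphenes(self) -> list[Phosphene]:
        return [
            Phosphene(float(x), float(y), float(s))
            for x, y, s in zip(self.x_deg, self.y_deg, self.sigma_deg)
        ]

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "tier": self.tier,
                "seed": self.seed,
                "rho_max_deg": self.rho_max_deg,
                "profile": self.profile.to_dict(),
                "phosphenes": [
                    {"x_deg": float(x), "y_deg": float(y), "sigma_deg": float(s)}
                    for x, y, s in zip(self.x_deg, self.y_deg, self.sigma_deg)
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhosphenePattern":
        d = json.loads(text)
        ph = d["phosphenes"]
        return cls(
            tier=d["tier"],
            seed=d["seed"],
            rho_max_deg=d["rho_max_deg"],
            profile=DensityProfile.from_dict(d["profile"]),
            x_deg=np.array([p["x_deg"] for p in ph]),
            y_deg=np.array([p["y_deg"] for p in ph]),
            sigma_deg=np.array([p["sigma_deg"] for p in ph]),
        )

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["x_deg", "y_deg", "sigma_deg"])
        for x, y, s in zip(self.x_deg, self.y_deg, self.sigma_deg):
            w.writerow([f"{x:.9g}", f"{y:.9g}", f"{s:.9g}"])
        return buf.getvalue()


def _inverse_cdf_sample(
    rng: np.random.Generator,
    n: int,
    shape,
    r_lo: float,
    r_hi: float,
) -> np.ndarray:
    """Draw n radii from the density r * shape(r) on [r_lo, r_hi]."""
    grid = np.linspace(r_lo, r_hi, 4097)
    pdf = grid * shape(grid)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def generate_pattern(
    tier: str,
    profile: DensityProfile | None = None,
    seed: int = 0,
) -> PhosphenePattern:
    """Draw a phosphene pattern for a density tier.

    Radii are drawn by inverse-CDF sampling of the radial density and
    angles uniformly, stratified so that the tier's total count and its
    count within 10 deg of the point of regard hold exactly for every
    seed.  Each phosphene's sigma follows the eccentricity law.
    Deterministic given ``seed``.
    """
    key = tier.lower()
    if key not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {sorted(TIERS)}")
    t = TIERS[key]
    if profile is None:
        profile = default_profile()
    boundary = profile.boundary_deg if profile.boundary_deg is not None else None

    rng = np.random.default_rng(seed)
    if boundary is None:
        # Single-stratum profile: only the total is enforced.
        rho = _inverse_cdf_sample(
            rng,
            t.total,
            lambda r: (1.0 + r / profile.rho0) ** (-profile.exponent),
            0.0,
            profile.rho_max_deg,
        )
    else:
        inner = _inverse_cdf_sample(
            rng,
            t.central,
            lambda r: (1.0 + r / profile.rho0) ** (-profile.exponent),
            0.0,
            boundary,
        )
        outer = _inverse_cdf_sample(
            rng,
            t.total - t.central,
            lambda r: (1.0 + r / profile.outer_rho0) ** (-profile.outer_exponent),
            np.nextafter(boundary, np.inf),
            profile.rho_max_deg,
        )
        rho = np.concatenate([inner, outer])
    theta = rng.uniform(0.0, 2.0 * math.pi, rho.size)
    x = rho * np.cos(theta)
    y = rho * np.sin(theta)
    return PhosphenePattern(
        tier=key,
        seed=int(seed),
        rho_max_deg=profile.rho_max_deg,
        profile=profile,
        x_deg=x,
        y_deg=y,
        sigma_deg=phosphene_sigma(rho),
    )


def count_in_window(pattern: PhosphenePattern, window: "Circle | Rect") -> int:
    """Number of phosphene centers inside a closed centered region."""
    if isinstance(window, Circle):
        return int(np.count_nonzero(pattern.eccentricity_deg <= window.radius_deg))
    if isinstance(window, Rect):
        inside = (np.abs(pattern.x_deg) <= window.width_deg / 2.0) & (
            np.abs(pattern.y_deg) <= window.height_deg / 2.0
        )
        return int(np.count_nonzero(inside))
    raise TypeError(f"unknown window type: {window!r}")


def perceptual_efficiency(pattern: PhosphenePattern, acuity_logmar: float) -> int:
    """Phosphenes within the circle spanning the just-readable letter.

    The circle's diameter is five times the MAR at the measured acuity
    (the five dark/light bands of the smallest identifiable letter E),
    i.e. ``5 * 10**acuity`` arcminutes.
    """
    if not math.isfinite(acuity_logmar):
        raise ValueError("acuity must be finite")
    diameter_deg = 5.0 * 10.0 ** acuity_logmar / 60.0
    return count_in_window(pattern, Circle(diameter_deg / 2.0))
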