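"""Sessile-drop wettability of tablet surfaces.

A small droplet (10 µL by default, small enough that gravity flattening
is negligible) is placed on the film-coated tablet and its silhouette is
modelled as a spherical cap resting on a flat baseline.  The apparent
contact angle θ at the droplet-solid-air tri-phase line follows from the
cap geometry::

    θ = 2 · arctan(h / a)

with apex height ``h`` and contact-line half-width (base radius) ``a``.
Equivalently, for the circle of radius ``R`` whose centre sits a height
``y_c`` above the baseline, ``θ = arccos(-y_c / R)``.

Angles at or below 90° signal a hydrophilic (wetting) surface, above 90°
a hydrophobic one.  The image route segments the droplet above a detected
baseline, fits a circle to the silhouette contour by least squares and
evaluates the tangent angle at the left and right tri-phase points; their
mean is reported and a large left/right disagreement rejects the fit (a
guard against tilted baselines and asymmetric silhouettes, standing in
for the axial-thinning correction used on real recordings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DropletGeometry",
    "ContactAngleResult",
    "WettabilityError",
    "NoDropletError",
    "NoBaselineError",
    "FitQualityError",
    "contact_angle_geometric",
    "spherical_cap_area",
    "contact_angle_from_image",
    "classify_wetting",
    "relative_reduction",
]


class WettabilityError(RuntimeError):
    """Base class for contact-angle estimation failures."""


class NoDropletError(WettabilityError):
    """No droplet silhouette could be segmented from the image."""


class NoBaselineError(WettabilityError):
    """No horizontal substrate baseline could be detected."""


class FitQualityError(WettabilityError):
    """The circle fit is unreliable (high residual or side disagreement)."""


@dataclass(frozen=True)
class DropletGeometry:
    """Spherical-cap droplet geometry: base radius and apex height in mm."""

    base_radius_mm: float
    apex_height_mm: float
    drop_volume_uL: float = 10.0

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be > 0")
        if self.apex_height_mm < 0:
            raise ValueError("apex_height_mm must be >= 0")


@dataclass(frozen=True)
class ContactAngleResult:
    """An apparent contact angle with its provenance and diagnostics."""

    angle_deg: float
    time_point_s: float = 0.0
    method: str = "geometric"
    wetting_class: str = "hydrophilic"
    left_angle_deg: float | None = None
    right_angle_deg: float | None = None
    fit_residual_px: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("angle must lie in [0, 180] degrees")


def contact_angle_geometric(geom: DropletGeometry) -> float:
    """Apparent contact angle (degrees) from cap geometry, 2·arctan(h/a)."""
    return math.degrees(2.0 * math.atan2(geom.apex_height_mm, geom.base_radius_mm))


def spherical_cap_area(geom: DropletGeometry) -> float:
    """Curved surface area of the spherical cap, π(a² + h²), in mm².

    Reduces to the flat-disc limit π·a² for a fully spread film (h = 0)
    and to the hemisphere area 2πR² when h = a = R.
    """
    return math.pi * (geom.base_radius_mm**2 + geom.apex_height_mm**2)


def classify_wetting(angle_deg: float) -> str:
    """``"hydrophilic"`` for angles ≤ 90°, ``"hydrophobic"`` above 90°."""
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    return "hydrophilic" if angle_deg <= 90.0 else "hydrophobic"


def relative_reduction(a: float, b: float) -> float:
    """Percent reduction from ``a`` to ``b``: ``(a - b) / a * 100``."""
    if a == 0:
        raise ZeroDivisionError("reference value a must be non-zero")
    return (a - b) / a * 100.0


def _fit_circle(cols: np.ndarray, rows: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares (Kåsa) circle fit; returns (c_col, c_row, R, rms)."""
    x = np.asarray(cols, dtype=float)
    y = np.asarray(rows, dtype=float)
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r_sq = c + cx**2 + cy**2
    if r_sq <= 0:
        raise FitQualityError("degenerate circle fit")
    R = math.sqrt(r_sq)
    residual = np.hypot(x - cx, y - cy) - R
    rms = float(np.sqrt(np.mean(residual**2)))
    return float(cx), float(cy), R, rms


def _angle_from_circle(c_row: float, R: float, baseline_y: float) -> float:
    """Tangent angle (deg) where the fitted circle crosses the baseline."""
    yc = baseline_y - c_row  # centre height above the baseline (+ up)
    if yc >= R:
        raise FitQualityError("fitted circle does not intersect the baseline")
    return math.degrees(math.acos(max(-1.0, min(1.0, -yc / R))))


def detect_baseline(image: np.ndarray, dark_threshold: float = 0.5) -> int:
    """Top row index of the substrate: first row that is ≥ 90 % dark."""
    dark_frac = (image < dark_threshold).mean(axis=1)
    rows = np.nonzero(dark_frac >= 0.9)[0]
    if rows.size == 0:
        raise NoBaselineError("baseline not detected")
    return int(rows[0])


def contact_angle_from_image(
    image: np.ndarray,
    scale_px_per_mm: float | None = None,
    time_point_s: float = 0.0,
    dark_threshold: float = 0.5,
    baseline_row: int | None = None,
    max_side_disagreement_deg: float = 5.0,
    max_residual_px: float = 2.0,
) -> ContactAngleResult:
    """Estimate the apparent contact angle from a sessile-drop image.

    The image is a grayscale frame (values in [0, 1] or [0, 255]) showing
    a dark droplet on a light background resting on a dark substrate
    strip.  The baseline is auto-detected (or forced with
    ``baseline_row``), the droplet contour above it is extracted at
    sub-pixel precision and a circle is fitted by least squares; the
    reported angle is the mean of the tangent angles at the left and
    right tri-phase points from independent half-contour fits.

    Raises
    ------
    NoBaselineError, NoDropletError, FitQualityError
        When the respective stage cannot produce a reliable estimate.
    """
    from skimage.measure import find_contours

    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.max() > 1.0:
        img = img / 255.0

    if baseline_row is None:
        baseline_row = detect_baseline(img, dark_threshold)
    if baseline_row < 5:
        raise NoBaselineError("baseline too close to the top of the frame")
    baseline_y = baseline_row - 0.5  # geometric substrate surface

    above = img[:baseline_row, :]
    if int((above < dark_threshold).sum()) < 50:
        raise NoDropletError("no droplet found above the baseline")

    contours = find_contours(above, level=dark_threshold)
    if not contours:
        raise NoDropletError("no droplet contour found")
    contour = max(contours, key=len)
    # drop points hugging the baseline cut so only the free arc is fitted
    keep = contour[:, 0] < baseline_row - 2.0
    pts = contour[keep]
    if pts.shape[0] < 10:
        raise NoDropletError("droplet contour too small to fit")

    rows, cols = pts[:, 0], pts[:, 1]
    cx, cy, R, rms = _fit_circle(cols, rows)
    if rms > max_residual_px:
        raise FitQualityError(f"circle-fit residual {rms:.2f} px exceeds {max_residual_px} px")

    halves = []
    for mask in (cols <= cx, cols >= cx):
        if int(mask.sum()) < 5:
            raise FitQualityError("too few contour points on one droplet side")
        _, hcy, hR, _ = _fit_circle(cols[mask], rows[mask])
        halves.append(_angle_from_circle(hcy, hR, baseline_y))
    left_angle, right_angle = halves
    if abs(left_angle - right_angle) > max_side_disagreement_deg:
        raise FitQualityError(
            f"left/right tangent angles disagree by "
            f"{abs(left_angle - right_angle):.2f}° (> {max_side_disagreement_deg}°)"
        )

    angle = (left_angle + right_angle) / 2.0
    return ContactAngleResult(
        angle_deg=angle,
        time_point_s=time_point_s,
        method="image",
        wetting_class=classify_wetting(angle),
        left_angle_deg=left_angle,
        right_angle_deg=right_angle,
        fit_residual_px=rms,
    )
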