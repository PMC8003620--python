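"""Coefficient of sliding friction from incline-ramp transit times.

A tablet released from rest slides down a saliva-wetted ramp of length
``L`` inclined at angle θ.  Under uniform acceleration the transit time
``t`` gives ``a = 2L / t²``.  The Coulomb model ``F_F = µ F_N`` applied to
the free body on the incline (normal force ``m g cosθ``, driving force
``m g sinθ``, no rolling or fluid drag) yields::

    µ = tanθ - a / (g cosθ)

The tablet mass cancels, so µ is a property of the surface pair alone.
An observed acceleration above the frictionless limit ``g sinθ`` is
physically inconsistent for gravity-driven sliding and is flagged, with
µ clamped to 0.  Because published friction readings on such rigs are
often reported in arbitrary, rig-normalised units, a *relative* mode is
provided that expresses a formulation's mean µ against a reference
formulation measured on the same geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RampTrial",
    "FrictionResult",
    "TrialSummary",
    "PhysicsWarning",
    "acceleration_from_transit",
    "coefficient_of_friction",
    "summarize_trials",
    "relative_cof",
]

#: Standard gravitational acceleration, m/s².
G_STANDARD = 9.81


class PhysicsWarning(UserWarning):
    """A trial is inconsistent with gravity-driven sliding."""


@dataclass(frozen=True)
class RampTrial:
    """One incline-ramp run: geometry, tablet mass and transit time.

    Defaults mirror the bench apparatus: 0.20 m ramp at 45°, a 500 mg
    tablet, saliva irrigation at 1 mL/s and g = 9.81 m/s².
    """

    transit_time_s: float
    ramp_length_m: float = 0.20
    incline_angle_deg: float = 45.0
    tablet_mass_kg: float = 5.0e-4
    saliva_flow_ml_s: float = 1.0
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        if self.transit_time_s <= 0:
            raise ValueError("transit_time_s must be > 0")
        if self.ramp_length_m <= 0 or self.tablet_mass_kg <= 0 or self.g <= 0:
            raise ValueError("ramp_length_m, tablet_mass_kg and g must be > 0")
        if not 0.0 < self.incline_angle_deg < 90.0:
            raise ValueError("incline_angle_deg must lie strictly between 0 and 90")

    def geometry(self) -> tuple[float, float, float]:
        return (self.ramp_length_m, self.incline_angle_deg, self.g)


@dataclass(frozen=True)
class FrictionResult:
    """Free-body quantities for one trial (SI units; µ dimensionless)."""

    acceleration: float
    normal_force: float
    friction_force: float
    mu: float
    clamped: bool = False


@dataclass(frozen=True)
class TrialSummary:
    """Per-formulation summary over replicate ramp runs."""

    mu_mean: float
    mu_std: float
    transit_mean_s: float
    transit_std_s: float
    n: int


def acceleration_from_transit(trial: RampTrial) -> float:
    """Uniform acceleration from rest over the ramp: ``a = 2L / t²`` (m/s²)."""
    return 2.0 * trial.ramp_length_m / trial.transit_time_s**2


def coefficient_of_friction(trial: RampTrial) -> FrictionResult:
    """Coulomb sliding-friction coefficient for one ramp trial.

    Computes ``F_N = m g cosθ``, ``F_F = m (g sinθ - a)`` and
    ``µ = F_F / F_N = tanθ - a / (g cosθ)``.  If the measured acceleration
    exceeds the frictionless limit ``g sinθ`` the trial is flagged with a
    :class:`PhysicsWarning` and µ is clamped to 0.
    """
    a = acceleration_from_transit(trial)
    theta = math.radians(trial.incline_angle_deg)
    g_sin = trial.g * math.sin(theta)
    normal = trial.tablet_mass_kg * trial.g * math.cos(theta)
    clamped = False
    if a > g_sin * (1.0 + 1e-12):
        warnings.warn(
            f"acceleration {a:.4g} m/s² exceeds frictionless limit "
            f"{g_sin:.4g} m/s²; clamping µ to 0",
            PhysicsWarning,
            stacklevel=2,
        )
        a = g_sin
        clamped = True
    friction = trial.tablet_mass_kg * (g_sin - a)
    return FrictionResult(
        acceleration=a,
        normal_force=normal,
        friction_force=friction,
        mu=friction / normal,
        clamped=clamped,
    )


def summarize_trials(trials: list[RampTrial]) -> TrialSummary:
    """Mean/std of µ and of transit ("mobility") time over replicates.

    All trials must share the same ramp geometry (length, angle, g);
    mixing geometries is rejected.  Standard deviations use ddof=1.
    """
    if not trials:
        raise ValueError("at least one trial is required")
    geom = trials[0].geometry()
    if any(t.geometry() != geom for t in trials[1:]):
        raise ValueError("trials mix different ramp geometries")
    mus = np.array([coefficient_of_friction(t).mu for t in trials])
    times = np.array([t.transit_time_s for t in trials])
    ddof = 1 if len(trials) > 1 else 0
    return TrialSummary(
        mu_mean=float(mus.mean()),
        mu_std=float(mus.std(ddof=ddof)),
        transit_mean_s=float(times.mean()),
        transit_std_s=float(times.std(ddof=ddof)),
        n=len(trials),
    )


def relative_cof(summary: TrialSummary, reference: TrialSummary) -> float:
    """Mean µ normalised to a reference formulation's mean µ."""
    if reference.mu_mean <= 0:
        raise ValueError("reference mean µ must be > 0 for normalisation")
    return summary.mu_mean / reference.mu_mean
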