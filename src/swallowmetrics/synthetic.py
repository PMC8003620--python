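"""Synthetic instrument-style data with known ground truth.

Generators for every pipeline stage, emulating the statistical structure
the analysis assumes:

* thickness time series - monotone saturating percent-change curves
  (optionally hard-plateauing), inverted through the gel-layer formula
  into thickness values with additive Gaussian replicate noise;
* film frames - rendered core/film/background disks whose hydrated
  front advances by known pixel amounts;
* sessile-drop images - anti-aliased spherical-cap silhouettes above a
  dark baseline with exactly known contact angle;
* ramp transit times - the closed-form inverse of the incline free-body
  chain, ``t = sqrt(2L / (g(sinθ - µ cosθ)))``, with multiplicative
  log-normal jitter (transit times are strictly positive);
* force-distance traces - a detachment spike (linear rise to the peak,
  linear stress-drop to a sliding plateau) with additive Gaussian noise;
  uncoated mode instead builds a stick-slip sawtooth with a requested
  number of large stress drops.  The analytic spike area is retained as
  ground truth for the work-of-adhesion integrator.

All randomness flows through ``numpy.random.default_rng(cfg.seed)``;
regeneration under the same seed is bit-identical.  Presets are shipped
for the eleven-formulation reference panel with plausible profiles
anchored to the reported summary values where available; they are
illustrative, not measured raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hydration import DEFAULT_TIME_GRID, FilmFrame, ThicknessSeries
from .ramp_friction import RampTrial
from .shear_adhesion import ForceTrace
from .study_tables import CONTACT_ANGLES_DEG, COF_AU

__all__ = [
    "GeneratorConfig",
    "FormulationProfile",
    "PRESETS",
    "SyntheticTrace",
    "gen_thickness_series",
    "gen_film_frames",
    "gen_droplet_image",
    "gen_blank_stage",
    "gen_ramp_times",
    "noiseless_transit_time",
    "gen_force_trace",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, noise level and coating mode shared by all generators.

    ``noise_sd`` is interpreted in each generator's signal units
    (µm for thickness, N for force, intensity for images); transit-time
    jitter is a separate fractional parameter.  ``mode`` switches the
    coated (single detachment spike, swelling film) and uncoated
    (stick-slip sawtooth, no swelling) regimes.
    """

    seed: int = 0
    noise_sd: float = 0.0
    mode: str = "coated"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("coated", "uncoated"):
            raise ValueError("mode must be 'coated' or 'uncoated'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class FormulationProfile:
    """Target ground-truth profile for one formulation preset.

    ``gl_plateau_pct``/``gl_rate_per_s``/``gl_saturate_s`` shape the
    gel-layer percent curve; ``theta_deg`` maps wetting time (s) to the
    target contact angle; ``mu`` is the incline sliding-friction target
    (< tan 45°); the force entries shape the shear-adhesion trace.
    """

    name: str
    mode: str = "coated"
    T0_um: float = 300.0
    gl_plateau_pct: float = 0.0
    gl_rate_per_s: float = 0.05
    gl_saturate_s: float | None = None
    theta_deg: dict[int, float] = field(default_factory=dict)
    mu: float | None = None
    peak_force_n: float = 0.3
    onset_force_n: float | None = 0.25
    plateau_force_n: float = 0.12
    n_drops: int = 0


def _angles(name: str) -> dict[int, float]:
    return {t: mean for t, (mean, _std) in CONTACT_ANGLES_DEG[name].items()}


def _preset_mu(name: str, fallback: float) -> float:
    # reported friction readings are rig-normalised a.u.; rescale into the
    # gravity-consistent range (< tan 45°) preserving the reported order
    return COF_AU[name] / 2.75 if name in COF_AU else fallback


#: Illustrative ground-truth profiles for the reference panel.
PRESETS: dict[str, FormulationProfile] = {
    "Unc": FormulationProfile(
        name="Unc", mode="uncoated", gl_plateau_pct=0.0,
        peak_force_n=0.85, onset_force_n=None, plateau_force_n=0.25, n_drops=7,
    ),
    "PVA": FormulationProfile(
        name="PVA", gl_plateau_pct=0.12, gl_rate_per_s=0.12, gl_saturate_s=24.0,
        theta_deg=_angles("PVA"), mu=_preset_mu("PVA", 0.578),
        peak_force_n=0.36, onset_force_n=0.30, plateau_force_n=0.17,
    ),
    "HPMC": FormulationProfile(
        name="HPMC", gl_plateau_pct=0.28, gl_rate_per_s=0.08, gl_saturate_s=40.0,
        theta_deg=_angles("HPMC"), mu=_preset_mu("HPMC", 0.570),
        peak_force_n=0.33, onset_force_n=0.27, plateau_force_n=0.16,
    ),
    "KIR": FormulationProfile(
        name="KIR", gl_plateau_pct=0.10, gl_rate_per_s=0.06,
        theta_deg=_angles("KIR"), mu=_preset_mu("KIR", 0.578),
        peak_force_n=0.34, onset_force_n=0.28, plateau_force_n=0.165,
    ),
    "OEZ": FormulationProfile(
        name="OEZ", gl_plateau_pct=0.28, gl_rate_per_s=0.10, gl_saturate_s=40.0,
        theta_deg=_angles("OEZ"), mu=_preset_mu("OEZ", 0.556),
        peak_force_n=0.18, onset_force_n=0.14, plateau_force_n=0.06,
    ),
    "C1": FormulationProfile(
        name="C1", gl_plateau_pct=0.90, gl_rate_per_s=0.05,
        theta_deg=_angles("C1"), mu=0.565,
        peak_force_n=0.24, onset_force_n=0.19, plateau_force_n=0.09,
    ),
    "C3": FormulationProfile(
        name="C3", gl_plateau_pct=1.10, gl_rate_per_s=0.055,
        theta_deg=_angles("C3"), mu=0.571,
        peak_force_n=0.25, onset_force_n=0.20, plateau_force_n=0.10,
    ),
    "Ge1": FormulationProfile(
        name="Ge1", gl_plateau_pct=1.20, gl_rate_per_s=0.045,
        theta_deg=_angles("Ge1"), mu=_preset_mu("Ge1", 0.575),
        peak_force_n=0.27, onset_force_n=0.21, plateau_force_n=0.11,
    ),
    "Ge3": FormulationProfile(
        name="Ge3", gl_plateau_pct=1.50, gl_rate_per_s=0.040,
        theta_deg=_angles("Ge3"), mu=_preset_mu("Ge3", 0.560),
        peak_force_n=0.26, onset_force_n=0.20, plateau_force_n=0.10,
    ),
    "Ge3C1": FormulationProfile(
        name="Ge3C1", gl_plateau_pct=1.50, gl_rate_per_s=0.055,
        theta_deg=_angles("Ge3C1"), mu=_preset_mu("Ge3C1", 0.560),
        peak_force_n=0.22, onset_force_n=0.17, plateau_force_n=0.08,
    ),
    "Ge3C3": FormulationProfile(
        name="Ge3C3", gl_plateau_pct=1.60, gl_rate_per_s=0.060,
        theta_deg=_angles("Ge3C3"), mu=_preset_mu("Ge3C3", 0.571),
        peak_force_n=0.23, onset_force_n=0.18, plateau_force_n=0.085,
    ),
}


# ---------------------------------------------------------------------------
# thickness series


def gen_thickness_series(
    T0_um: float,
    plateau_pct: float,
    rate_per_s: float,
    cfg: GeneratorConfig,
    grid_s: np.ndarray | None = None,
    n_replicates: int = 6,
    saturate_at_s: float | None = None,
    formulation_id: str = "synthetic",
) -> ThicknessSeries:
    """Saturating gel-layer growth inverted into a thickness series.

    The percent-change curve is ``p(t) = P·(1 - exp(-k·t))`` (plateau
    ``P`` in %, rate ``k`` in 1/s), optionally clamped to its value at
    ``saturate_at_s`` for all later times (a hard plateau).  Thickness
    follows by inverting the current-denominator percent formula:
    ``T(t) = T0 / (1 - p(t)/100)``.  Gaussian noise of sd
    ``cfg.noise_sd`` (µm) is added per replicate; uncoated mode yields a
    constant series (no measurable swelling).
    """
    if rate_per_s < 0:
        raise ValueError("rate_per_s must be >= 0")
    if plateau_pct < 0:
        raise ValueError("plateau_pct must be >= 0")
    if plateau_pct >= 100:
        raise ValueError("plateau_pct must be < 100 for an invertible curve")
    times = DEFAULT_TIME_GRID.copy() if grid_s is None else np.asarray(grid_s, float)
    if cfg.mode == "uncoated" or plateau_pct == 0:
        pct = np.zeros_like(times)
    else:
        pct = plateau_pct * (1.0 - np.exp(-rate_per_s * times))
        if saturate_at_s is not None:
            pct = np.where(
                times >= saturate_at_s,
                plateau_pct * (1.0 - math.exp(-rate_per_s * saturate_at_s)),
                pct,
            )
    thickness = T0_um / (1.0 - pct / 100.0)
    rng = cfg.rng()
    reps = np.tile(thickness, (n_replicates, 1))
    if cfg.noise_sd > 0:
        reps = reps + rng.normal(0.0, cfg.noise_sd, size=reps.shape)
        reps = np.maximum(reps, 1e-6)
    return ThicknessSeries(
        formulation_id=formulation_id, times=times, thickness=reps, T0=T0_um
    )


# ---------------------------------------------------------------------------
# film frames


def _disk_coverage(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Anti-aliased disk membership in [0, 1] (1-px soft edge)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    return np.clip(0.5 - (dist - radius), 0.0, 1.0)


def gen_film_frames(
    T0_um: float,
    growth_um: np.ndarray,
    timestamps_s: np.ndarray,
    cfg: GeneratorConfig,
    scale_px_per_mm: float = 100.0,
    core_radius_mm: float = 1.0,
    blank: set[int] | None = None,
) -> list[FilmFrame]:
    """Render frames of a hydrating film with known front positions.

    Each frame shows a bright core disk of fixed radius surrounded by a
    film annulus whose outer radius advances with the hydrated-front
    distance ``T0_um + growth_um[i]``.  Frame indices listed in
    ``blank`` are rendered featureless (segmentation-failure cases).
    """
    growth_um = np.asarray(growth_um, float)
    timestamps_s = np.asarray(timestamps_s, float)
    if growth_um.shape != timestamps_s.shape:
        raise ValueError("growth_um and timestamps_s must have equal length")
    px_per_um = scale_px_per_mm / 1000.0
    core_px = core_radius_mm * scale_px_per_mm
    max_outer = core_px + (T0_um + growth_um.max()) * px_per_um
    side = int(math.ceil(2 * max_outer + 20))
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    rng = cfg.rng()
    frames = []
    for i, (g, t) in enumerate(zip(growth_um, timestamps_s)):
        if blank and i in blank:
            img = np.full((side, side), 0.1)
        else:
            outer_px = core_px + (T0_um + g) * px_per_um
            film = _disk_coverage((side, side), center, outer_px)
            core = _disk_coverage((side, side), center, core_px)
            img = 0.1 + 0.45 * film + 0.4 * core
        if cfg.noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, cfg.noise_sd, img.shape), 0.0, 1.0)
        frames.append(FilmFrame(image=img, scale=scale_px_per_mm, timestamp=float(t)))
    return frames


# ---------------------------------------------------------------------------
# droplet images


def gen_droplet_image(
    theta_true_deg: float,
    base_px: float,
    cfg: GeneratorConfig,
    substrate_px: int = 12,
    margin_px: int = 40,
) -> np.ndarray:
    """Render a sessile-drop silhouette with exact contact angle.

    A dark spherical-cap silhouette (intensity 0.08) on a light
    background (0.95) resting on a dark substrate strip, with a 1-px
    anti-aliased edge; ``base_px`` is the contact-line width in pixels.
    Gaussian intensity noise of sd ``cfg.noise_sd`` is added when
    requested.  Returns a float image in [0, 1].
    """
    if not 5.0 <= theta_true_deg <= 175.0:
        raise ValueError("theta_true_deg must lie in [5, 175] degrees")
    a = base_px / 2.0
    h = a * math.tan(math.radians(theta_true_deg) / 2.0)
    R = (a * a + h * h) / (2.0 * h)
    yc = h - R  # centre height above the baseline (+ up)
    half_width = a if theta_true_deg <= 90 else R

    width = int(math.ceil(2 * half_width + 2 * margin_px))
    height = int(math.ceil(h + margin_px + substrate_px))
    b0 = height - substrate_px  # first substrate row
    y_base = b0 - 0.5
    cx = (width - 1) / 2.0
    c_row = y_base - yc

    rr, cc = np.mgrid[0:height, 0:width]
    dist = np.hypot(rr - c_row, cc - cx)
    coverage = np.clip(0.5 - (dist - R), 0.0, 1.0)
    coverage[rr >= b0] = 0.0
    img = 0.95 - 0.87 * coverage
    img[rr >= b0] = 0.08

    if cfg.noise_sd > 0:
        img = np.clip(img + cfg.rng().normal(0.0, cfg.noise_sd, img.shape), 0.0, 1.0)
    return img


def gen_blank_stage(cfg: GeneratorConfig, size: tuple[int, int] = (120, 200)) -> np.ndarray:
    """Render a droplet-free stage (substrate strip only).

    Emulates a disintegrating core on which no stable droplet forms;
    contact-angle estimation on this image raises a no-droplet error.
    """
    height, width = size
    img = np.full((height, width), 0.95)
    img[height - 12 :, :] = 0.08
    if cfg.noise_sd > 0:
        img = np.clip(img + cfg.rng().normal(0.0, cfg.noise_sd, img.shape), 0.0, 1.0)
    return img


# ---------------------------------------------------------------------------
# ramp transit times


def noiseless_transit_time(
    mu_true: float,
    ramp_length_m: float = 0.20,
    incline_angle_deg: float = 45.0,
    g: float = 9.81,
) -> float:
    """Closed-form transit time ``t = sqrt(2L / (g(sinθ - µ cosθ)))``."""
    theta = math.radians(incline_angle_deg)
    if mu_true >= math.tan(theta):
        raise ValueError("mu_true must be < tan(incline angle): tablet would not slide")
    denom = g * (math.sin(theta) - mu_true * math.cos(theta))
    return math.sqrt(2.0 * ramp_length_m / denom)


def gen_ramp_times(
    mu_true: float,
    cfg: GeneratorConfig,
    n_trials: int = 6,
    jitter: float = 0.0,
    ramp_length_m: float = 0.20,
    incline_angle_deg: float = 45.0,
    tablet_mass_kg: float = 5.0e-4,
    g: float = 9.81,
) -> list[RampTrial]:
    """Generate replicate ramp trials consistent with a true µ.

    Transit times take multiplicative log-normal jitter of fractional
    scale ``jitter`` (times stay positive); ``jitter=0`` reproduces the
    closed form exactly, so the friction estimator recovers ``mu_true``
    to machine precision.
    """
    if mu_true < 0:
        raise ValueError("mu_true must be >= 0")
    t0 = noiseless_transit_time(mu_true, ramp_length_m, incline_angle_deg, g)
    rng = cfg.rng()
    trials = []
    for _ in range(n_trials):
        factor = math.exp(rng.normal(0.0, jitter)) if jitter > 0 else 1.0
        trials.append(
            RampTrial(
                transit_time_s=t0 * factor,
                ramp_length_m=ramp_length_m,
                incline_angle_deg=incline_angle_deg,
                tablet_mass_kg=tablet_mass_kg,
                g=g,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# force traces


@dataclass(frozen=True)
class SyntheticTrace:
    """A generated force trace with its analytic ground truth."""

    trace: ForceTrace
    peak_force_n: float
    plateau_force_n: float
    onset_force_n: float | None
    spike_area_mJ: float  #: analytic area over [spike start, stress-drop end]
    n_drops: int = 0


def gen_force_trace(
    peak_n: float,
    plateau_n: float,
    cfg: GeneratorConfig,
    spike_center_mm: float = 5.0,
    spike_width_mm: float = 1.5,
    onset_force_n: float | None = None,
    n_samples: int = 1001,
    extension_mm: float = 50.0,
    substrate: str = "sodium_polyacrylate",
    normal_force_n: float = 0.5,
    n_drops: int = 7,
) -> SyntheticTrace:
    """Generate a shear-adhesion trace with known spike geometry.

    Coated mode: force is zero before the spike onset at
    ``spike_center - spike_width`` (or steps to ``onset_force_n`` there),
    rises linearly to ``peak_n`` at the spike centre, falls linearly to
    ``plateau_n`` over ``spike_width`` and then holds the sliding
    plateau.  The analytic trapezoidal area of the spike region is
    retained as the work-of-adhesion ground truth (N·mm = mJ).

    Uncoated mode: a stick-slip sawtooth with ``n_drops`` teeth, the
    first tooth carrying the global maximum ``peak_n``; every tooth
    falls far enough that the stress-drop counter registers exactly
    ``n_drops`` events.
    """
    if not peak_n >= plateau_n >= 0:
        raise ValueError("require peak_n >= plateau_n >= 0")
    x = np.linspace(0.0, extension_mm, n_samples)
    rng = cfg.rng()

    if cfg.mode == "uncoated":
        f = np.full_like(x, 0.03 * peak_n)
        centers = np.linspace(3.0, extension_mm * 0.9, n_drops)
        half = min(1.2, 0.4 * (centers[1] - centers[0]) if n_drops > 1 else 1.2)
        heights = np.concatenate(
            [[peak_n], rng.uniform(0.65, 0.95, size=n_drops - 1) * peak_n]
        )
        for c, hgt in zip(centers, heights):
            tooth = np.clip(1.0 - np.abs(x - c) / half, 0.0, 1.0) * hgt
            f = np.maximum(f, tooth)
        spike_area = 0.0
        onset_force_n = None
    else:
        x0 = spike_center_mm - spike_width_mm
        x1 = spike_center_mm + spike_width_mm
        if x0 < 0 or x1 > extension_mm:
            raise ValueError("spike lies outside the extension range")
        start = onset_force_n if onset_force_n is not None else 0.0
        if not peak_n >= start >= 0:
            raise ValueError("onset_force_n must lie in [0, peak_n]")
        f = np.zeros_like(x)
        rise = (x >= x0) & (x < spike_center_mm)
        f[rise] = start + (peak_n - start) * (x[rise] - x0) / spike_width_mm
        fall = (x >= spike_center_mm) & (x < x1)
        f[fall] = peak_n + (plateau_n - peak_n) * (x[fall] - spike_center_mm) / spike_width_mm
        f[x >= x1] = plateau_n
        spike_area = 0.5 * spike_width_mm * (start + peak_n) + 0.5 * spike_width_mm * (
            peak_n + plateau_n
        )
        n_drops = 0

    if cfg.noise_sd > 0:
        f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
    trace = ForceTrace(
        distance=x,
        force=f,
        substrate=substrate,
        normal_force=normal_force_n,
        extension_range=extension_mm,
    )
    return SyntheticTrace(
        trace=trace,
        peak_force_n=peak_n,
        plateau_force_n=plateau_n,
        onset_force_n=onset_force_n,
        spike_area_mJ=spike_area,
        n_drops=n_drops,
    )
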