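"""End-to-end study driver: manifest in, swallowability matrix out.

A *study manifest* (JSON) lists, per formulation, the thickness CSV,
droplet images (with wetting-time tags), ramp-trial CSV and force-trace
CSV, plus a global configuration block (contact area, gravitational
acceleration, pixel calibration, SI transit-time grid).  The pipeline
runs the four analytical stages, assembles per-time
:class:`~swallowmetrics.swallowability.SwallowabilityRecord` entries and
builds the colour-banded matrix.  A stage failure for one formulation is
logged and leaves that formulation's affected cells missing; the other
formulations are unaffected.

The contact angle entering the index at transit time *t* is linearly
interpolated between the measured wetting time points (0/10/20 s),
clamped at the ends; the work of adhesion, peak force and friction
coefficient are time-independent per formulation.

:func:`generate_study` writes a fully synthetic study (all reference
presets, fixed seed) in exactly the file dialects the pipeline reads, so
the whole chain can be exercised without instrument data; the pipeline
output is a pure function of (manifest, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as smio
from .hydration import gel_layer_change
from .ramp_friction import summarize_trials
from .shear_adhesion import CONTACT_AREA_MM2, adhesion_metrics
from .swallowability import (
    SI_TIMES_S,
    SwallowabilityMatrix,
    SwallowabilityRecord,
    build_matrix,
)
from .synthetic import (
    PRESETS,
    GeneratorConfig,
    gen_droplet_image,
    gen_force_trace,
    gen_ramp_times,
    gen_thickness_series,
)
from .wettability import WettabilityError, contact_angle_from_image

__all__ = [
    "StudyConfig",
    "FormulationPaths",
    "StudyManifest",
    "PipelineResult",
    "load_manifest",
    "run_pipeline",
    "generate_study",
    "run_synthetic_study",
]

log = logging.getLogger("swallowmetrics")


@dataclass(frozen=True)
class StudyConfig:
    """Global apparatus settings shared across a study.

    ``gl_detect_sigma`` controls the swelling detectability test: a
    series whose total thickness change is below this many standard
    errors of the replicate scatter shows no measurable swelling (e.g.
    an uncoated core) and is recorded as GL = 0 throughout, which
    propagates SI = 0.  ``wa_index_scale`` converts the J/mm² work of
    adhesion onto the scale at which it enters the index; the default
    1e6 expresses Wa in J/m², the magnitude scale of the
    reference-panel values, keeping index values inside the
    interpretable 0-10 band range.
    """

    contact_area_mm2: float = CONTACT_AREA_MM2
    g: float = 9.81
    scale_px_per_mm: float = 50.0
    si_times_s: tuple[float, ...] = SI_TIMES_S
    gl_detect_sigma: float = 4.0
    wa_index_scale: float = 1.0e6


@dataclass
class FormulationPaths:
    """Per-formulation input files; any entry may be absent (None)."""

    thickness_csv: Path | None = None
    droplets: list[tuple[float, Path]] = field(default_factory=list)
    ramp_csv: Path | None = None
    trace_csv: Path | None = None


@dataclass
class StudyManifest:
    formulations: dict[str, FormulationPaths]
    config: StudyConfig = field(default_factory=StudyConfig)


@dataclass
class PipelineResult:
    """Everything the study produced: records, matrix, tables, failures."""

    records: list[SwallowabilityRecord]
    matrix: SwallowabilityMatrix
    contact_angle_table: dict[str, dict[float, float]]
    hydration_table: dict[str, dict[float, float]]
    friction_table: dict[str, float]
    adhesion_table: dict[str, dict[str, float]]
    failures: dict[str, list[str]]
    missing: dict[str, list[str]]

    @property
    def ok(self) -> bool:
        """True when no provided input failed (absent inputs are allowed)."""
        return not any(self.failures.values())


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a JSON study manifest; relative paths resolve to its folder."""
    path = Path(path)
    raw = json.loads(path.read_text(encoding="utf-8"))
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return None if p is None else (base / p)

    cfg_raw = raw.get("config", {})
    config = StudyConfig(
        contact_area_mm2=float(cfg_raw.get("contact_area_mm2", CONTACT_AREA_MM2)),
        g=float(cfg_raw.get("g", 9.81)),
        scale_px_per_mm=float(cfg_raw.get("scale_px_per_mm", 50.0)),
        si_times_s=tuple(cfg_raw.get("si_times_s", SI_TIMES_S)),
        gl_detect_sigma=float(cfg_raw.get("gl_detect_sigma", 4.0)),
        wa_index_scale=float(cfg_raw.get("wa_index_scale", 1.0e6)),
    )
    formulations: dict[str, FormulationPaths] = {}
    for fid, entry in raw["formulations"].items():
        if fid in formulations:
            raise ValueError(f"duplicate formulation id {fid!r}")
        formulations[fid] = FormulationPaths(
            thickness_csv=resolve(entry.get("thickness_csv")),
            droplets=[(float(d["time_s"]), base / d["path"]) for d in entry.get("droplets", [])],
            ramp_csv=resolve(entry.get("ramp_csv")),
            trace_csv=resolve(entry.get("trace_csv")),
        )
    return StudyManifest(formulations=formulations, config=config)


def _swelling_detected(series, n_sigma: float) -> bool:
    """True when the final thickness change clears the replicate noise.

    Compares the mean change between the last and first grid points with
    ``n_sigma`` standard errors of the replicate scatter; exact-zero
    noiseless series pass through (their GL is 0 anyway).
    """
    first = series.thickness[:, 0]
    last = series.thickness[:, -1]
    delta = float(last.mean() - first.mean())
    n = series.n_replicates
    if n < 2:
        return True  # no scatter estimate; trust the measurement
    se = float(np.sqrt(first.var(ddof=1) / n + last.var(ddof=1) / n))
    return delta > n_sigma * se


def _interp_angle(angles: dict[float, float], t: float) -> float | None:
    if not angles:
        return None
    ts = sorted(angles)
    vals = [angles[x] for x in ts]
    return float(np.interp(t, ts, vals))


def run_pipeline(manifest: StudyManifest) -> PipelineResult:
    """Run all four analytical stages and assemble the matrix."""
    cfg = manifest.config
    records: list[SwallowabilityRecord] = []
    ca_table: dict[str, dict[float, float]] = {}
    gl_table: dict[str, dict[float, float]] = {}
    mu_table: dict[str, float] = {}
    adh_table: dict[str, dict[str, float]] = {}
    failures: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}

    for fid, paths in manifest.formulations.items():
        errs: list[str] = []
        absent: list[str] = []

        gl_by_time: dict[float, float] = {}
        if paths.thickness_csv is not None:
            try:
                series = smio.read_thickness_csv(paths.thickness_csv, formulation_id=fid)
                swelled = _swelling_detected(series, cfg.gl_detect_sigma)
                for t in cfg.si_times_s:
                    idx = np.nonzero(np.isclose(series.times, t))[0]
                    if idx.size:
                        gl = gel_layer_change(series, int(idx[0])) if swelled else 0.0
                        gl_by_time[float(t)] = max(gl, 0.0)
                log.info("%s: gel-layer change at %s", fid, gl_by_time)
            except Exception as exc:  # noqa: BLE001 - stage isolation
                errs.append(f"hydration: {exc}")
        else:
            absent.append("hydration")
        gl_table[fid] = gl_by_time

        angles: dict[float, float] = {}
        for t, img_path in paths.droplets:
            try:
                result = contact_angle_from_image(
                    smio.load_image(img_path),
                    scale_px_per_mm=cfg.scale_px_per_mm,
                    time_point_s=t,
                )
                angles[t] = result.angle_deg
                log.info("%s: contact angle %.2f deg at %gs (residual %.3f px)",
                         fid, result.angle_deg, t, result.fit_residual_px)
            except WettabilityError as exc:
                errs.append(f"wettability t={t:g}s: {exc}")
        ca_table[fid] = angles

        mu = None
        if paths.ramp_csv is not None:
            try:
                groups = smio.read_ramp_trials_csv(paths.ramp_csv)
                trials = groups.get(fid) or next(iter(groups.values()))
                summary = summarize_trials(trials)
                mu = summary.mu_mean
                mu_table[fid] = mu
                log.info("%s: mu=%.4f +/- %.4f (n=%d)", fid, summary.mu_mean,
                         summary.mu_std, summary.n)
            except Exception as exc:  # noqa: BLE001
                errs.append(f"ramp: {exc}")
        else:
            absent.append("ramp")

        wa = peak = None
        if paths.trace_csv is not None:
            try:
                trace = smio.read_force_trace_csv(paths.trace_csv)
                metrics = adhesion_metrics(trace, contact_area_mm2=cfg.contact_area_mm2)
                wa, peak = metrics.work_of_adhesion, metrics.peak_force
                adh_table[fid] = {
                    "peak_force_N": metrics.peak_force,
                    "work_of_adhesion_J_mm2": metrics.work_of_adhesion,
                    "mu_static": metrics.mu_static,
                    "mu_dynamic": metrics.mu_dynamic,
                    "stick_slip_events": metrics.stick_slip_count,
                }
                log.info("%s: adhesion %s", fid, adh_table[fid])
            except Exception as exc:  # noqa: BLE001
                errs.append(f"adhesion: {exc}")
        else:
            absent.append("adhesion")

        for t in cfg.si_times_s:
            gl = gl_by_time.get(float(t))
            records.append(
                SwallowabilityRecord(
                    formulation_id=fid,
                    time_s=float(t),
                    GL=gl,
                    CA=_interp_angle(angles, float(t)),
                    Wa=None if wa is None else wa * cfg.wa_index_scale,
                    F=peak,
                    CoF=mu,
                )
            )
        failures[fid] = errs
        missing[fid] = absent
        if absent:
            log.info("%s: no input for stages %s", fid, absent)

    return PipelineResult(
        records=records,
        matrix=build_matrix(records),
        contact_angle_table=ca_table,
        hydration_table=gl_table,
        friction_table=mu_table,
        adhesion_table=adh_table,
        failures=failures,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# synthetic study


def generate_study(
    out_dir: str | Path,
    seed: int = 0,
    noise_thickness_um: float = 0.1,
    noise_force_n: float = 0.005,
    noise_image: float = 0.01,
    ramp_jitter: float = 0.02,
    droplet_base_px: int = 160,
) -> Path:
    """Write a synthetic eleven-formulation study and return its manifest.

    One seed drives all generators (each formulation/stage draws from a
    distinct stream derived from it), so regeneration is bit-identical.
    The uncoated control deliberately has no ramp file (its friction
    cannot be measured once the core disintegrates) and droplet-free
    stage images; its swallowability index is still 0 by the GL = 0 rule.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = StudyConfig(scale_px_per_mm=50.0)
    manifest: dict = {
        "config": {
            "contact_area_mm2": config.contact_area_mm2,
            "g": config.g,
            "scale_px_per_mm": config.scale_px_per_mm,
            "si_times_s": list(config.si_times_s),
        },
        "formulations": {},
    }
    root = np.random.default_rng(seed)
    for fid, profile in PRESETS.items():
        sub = out / fid
        sub.mkdir(exist_ok=True)
        entry: dict = {}
        stage_seeds = root.integers(0, 2**31 - 1, size=4)

        series = gen_thickness_series(
            T0_um=profile.T0_um,
            plateau_pct=profile.gl_plateau_pct,
            rate_per_s=profile.gl_rate_per_s,
            saturate_at_s=profile.gl_saturate_s,
            cfg=GeneratorConfig(
                seed=int(stage_seeds[0]), noise_sd=noise_thickness_um, mode=profile.mode
            ),
            formulation_id=fid,
        )
        smio.write_thickness_csv(series, sub / "thickness.csv")
        entry["thickness_csv"] = f"{fid}/thickness.csv"

        droplets = []
        for k, (t, theta) in enumerate(sorted(profile.theta_deg.items())):
            img = gen_droplet_image(
                theta, base_px=droplet_base_px,
                cfg=GeneratorConfig(seed=int(stage_seeds[1]) + k, noise_sd=noise_image),
            )
            smio.save_image(img, sub / f"droplet_t{t}.png")
            droplets.append({"time_s": t, "path": f"{fid}/droplet_t{t}.png"})
        entry["droplets"] = droplets  # uncoated: no stable droplet, so none rendered

        if profile.mu is not None:
            trials = gen_ramp_times(
                profile.mu,
                cfg=GeneratorConfig(seed=int(stage_seeds[2])),
                jitter=ramp_jitter,
            )
            smio.write_ramp_trials_csv({fid: trials}, sub / "ramp.csv")
            entry["ramp_csv"] = f"{fid}/ramp.csv"

        synth = gen_force_trace(
            peak_n=profile.peak_force_n,
            plateau_n=profile.plateau_force_n,
            onset_force_n=profile.onset_force_n,
            n_drops=profile.n_drops or 7,
            cfg=GeneratorConfig(
                seed=int(stage_seeds[3]), noise_sd=noise_force_n, mode=profile.mode
            ),
        )
        smio.write_force_trace_csv(synth.trace, sub / "trace.csv")
        entry["trace_csv"] = f"{fid}/trace.csv"

        manifest["formulations"][fid] = entry

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest_path


def run_synthetic_study(seed: int = 0, workdir: str | Path | None = None, **gen_kwargs) -> PipelineResult:
    """Generate a synthetic study and run the full pipeline on it."""
    import tempfile

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            manifest_path = generate_study(tmp, seed=seed, **gen_kwargs)
            return run_pipeline(load_manifest(manifest_path))
    manifest_path = generate_study(workdir, seed=seed, **gen_kwargs)
    return run_pipeline(load_manifest(manifest_path))
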