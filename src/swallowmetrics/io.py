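"""Readers and writers for the plain-text instrument formats.

* thickness CSV: ``time_s,replicate,thickness_um`` (header required,
  UTF-8, dot decimal);
* ramp-trial CSV: ``formulation_id,ramp_length_m,angle_deg,mass_kg,transit_time_s``;
* force-trace CSV: ``distance_mm,force_N`` with an optional ``# key: value``
  header block (or JSON sidecar) carrying substrate / normal force /
  test speed metadata;
* grayscale PNG/TIFF images, loaded as float arrays in [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .hydration import ThicknessSeries
from .ramp_friction import RampTrial
from .shear_adhesion import ForceTrace

__all__ = [
    "read_thickness_csv",
    "write_thickness_csv",
    "read_ramp_trials_csv",
    "write_ramp_trials_csv",
    "read_force_trace_csv",
    "write_force_trace_csv",
    "load_image",
    "save_image",
]


def read_thickness_csv(path: str | Path, formulation_id: str | None = None) -> ThicknessSeries:
    """Load a replicated thickness series from ``time_s,replicate,thickness_um``."""
    df = pd.read_csv(path)
    required = {"time_s", "replicate", "thickness_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    wide = df.pivot(index="replicate", columns="time_s", values="thickness_um")
    wide = wide.sort_index(axis=1)
    if wide.isna().any().any():
        raise ValueError(f"{path}: replicates do not share a common time grid")
    return ThicknessSeries(
        formulation_id=formulation_id or Path(path).stem,
        times=wide.columns.to_numpy(dtype=float),
        thickness=wide.to_numpy(dtype=float),
    )


def write_thickness_csv(series: ThicknessSeries, path: str | Path) -> None:
    rows = []
    for rep in range(series.n_replicates):
        for j, t in enumerate(series.times):
            rows.append((t, rep + 1, series.thickness[rep, j]))
    pd.DataFrame(rows, columns=["time_s", "replicate", "thickness_um"]).to_csv(
        path, index=False
    )


def read_ramp_trials_csv(path: str | Path) -> dict[str, list[RampTrial]]:
    """Load ramp trials grouped by formulation id."""
    df = pd.read_csv(path)
    required = {"formulation_id", "ramp_length_m", "angle_deg", "mass_kg", "transit_time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, list[RampTrial]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.formulation_id), []).append(
            RampTrial(
                transit_time_s=float(row.transit_time_s),
                ramp_length_m=float(row.ramp_length_m),
                incline_angle_deg=float(row.angle_deg),
                tablet_mass_kg=float(row.mass_kg),
            )
        )
    return out


def write_ramp_trials_csv(trials: dict[str, list[RampTrial]], path: str | Path) -> None:
    rows = [
        (fid, t.ramp_length_m, t.incline_angle_deg, t.tablet_mass_kg, t.transit_time_s)
        for fid, ts in trials.items()
        for t in ts
    ]
    pd.DataFrame(
        rows,
        columns=["formulation_id", "ramp_length_m", "angle_deg", "mass_kg", "transit_time_s"],
    ).to_csv(path, index=False)


def _parse_header_block(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_force_trace_csv(path: str | Path, sidecar: str | Path | None = None) -> ForceTrace:
    """Load a force-distance trace with its metadata.

    Metadata keys ``substrate``, ``normal_force_N``, ``speed_mm_min`` and
    ``extension_range_mm`` are read from ``# key: value`` header lines or,
    if given, a JSON sidecar (the sidecar wins on conflicts).
    """
    path = Path(path)
    meta = _parse_header_block(path)
    if sidecar is not None:
        meta.update({k: str(v) for k, v in json.loads(Path(sidecar).read_text()).items()})
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"distance_mm", "force_N"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns distance_mm,force_N")
    kwargs = {}
    if "substrate" in meta:
        kwargs["substrate"] = meta["substrate"]
    if "normal_force_N" in meta:
        kwargs["normal_force"] = float(meta["normal_force_N"])
    if "speed_mm_min" in meta:
        kwargs["speed_mm_min"] = float(meta["speed_mm_min"])
    if "extension_range_mm" in meta:
        kwargs["extension_range"] = float(meta["extension_range_mm"])
    return ForceTrace(
        distance=df["distance_mm"].to_numpy(float),
        force=df["force_N"].to_numpy(float),
        **kwargs,
    )


def write_force_trace_csv(trace: ForceTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# substrate: {trace.substrate}\n")
        fh.write(f"# normal_force_N: {trace.normal_force!r}\n")
        fh.write(f"# speed_mm_min: {trace.speed_mm_min!r}\n")
        fh.write(f"# extension_range_mm: {trace.extension_range!r}\n")
        fh.write("distance_mm,force_N\n")
        for d, f in zip(trace.distance, trace.force):
            fh.write(f"{float(d)!r},{float(f)!r}\n")


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as a float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save a float image in [0, 1] as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)
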