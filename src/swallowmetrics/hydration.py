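"""Hydrated film-coat thickness kinetics.

When a film-coated tablet meets saliva, the coat imbibes liquid and a gel
layer grows outward from the dry core.  This module quantifies that growth
from replicated thickness time series (or from calibrated image frames of
the swelling front) with two descriptive percent metrics:

* **gel-layer change** at time index ``n``: ``(T_n - T_0) / T_n * 100``,
  the change relative to the *current* hydrated thickness.  The more
  conventional swelling ratio divides by the *initial* thickness ``T_0``;
  both conventions are available via ``denominator=`` and the
  current-thickness form is the default.
* **cumulative change**: the running sum of the per-interval terms
  ``(T_i - T_0) / T_i * 100`` for ``i = 1..n``.

A saturating ("plateau") regime is typical: the percent change rises and
then flattens once the gel layer stops advancing.  :func:`plateau_time`
detects the earliest onset of that flat regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_TIME_GRID",
    "ThicknessSeries",
    "FilmFrame",
    "SegmentationError",
    "gel_layer_change",
    "cumulative_change",
    "plateau_time",
    "film_front_um",
    "thickness_from_frames",
]

#: Default immersion sampling grid: 0-60 s in 4 s steps.
DEFAULT_TIME_GRID = np.arange(0.0, 61.0, 4.0)


class SegmentationError(RuntimeError):
    """Raised when no film/core boundary can be segmented from a frame."""


@dataclass
class ThicknessSeries:
    """Replicated film-coat thickness measurements on a common time grid.

    Parameters
    ----------
    formulation_id : str
        Label of the coating formulation.
    times : array-like of float
        Strictly increasing sampling times in seconds; ``times[0]`` is the
        instant the initial thickness ``T0`` refers to.
    thickness : array-like of float
        Thickness in micrometres, shape ``(n_replicates, n_times)`` (a 1-D
        array is treated as a single replicate).  All values must be > 0.
    T0 : float, optional
        Initial (dry/just-wetted) thickness in micrometres.  Defaults to
        the replicate mean at ``times[0]``.
    """

    formulation_id: str
    times: np.ndarray
    thickness: np.ndarray
    T0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.thickness = np.atleast_2d(np.asarray(self.thickness, dtype=float))
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.thickness.shape[1] != self.times.size:
            raise ValueError(
                f"thickness has {self.thickness.shape[1]} time points, "
                f"times has {self.times.size}"
            )
        if not np.all(np.isfinite(self.thickness)) or np.any(self.thickness <= 0):
            raise ValueError("all thickness values must be finite and > 0")
        if self.T0 is None:
            self.T0 = float(self.thickness[:, 0].mean())
        elif self.T0 <= 0:
            raise ValueError("T0 must be > 0")

    @property
    def n_replicates(self) -> int:
        return self.thickness.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Replicate-mean thickness per time point (µm)."""
        return self.thickness.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        """Replicate standard deviation per time point (µm, ddof=1)."""
        ddof = 1 if self.n_replicates > 1 else 0
        return self.thickness.std(axis=0, ddof=ddof)


@dataclass
class FilmFrame:
    """One calibrated grayscale frame of a hydrating film-coated tablet.

    ``image`` is a 2-D intensity grid (any numeric range), ``scale`` is the
    calibration in pixels per millimetre and ``timestamp`` the acquisition
    time in seconds.
    """

    image: np.ndarray
    scale: float
    timestamp: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.scale <= 0:
            raise ValueError("scale (px/mm) must be > 0")


def _index_for(series: ThicknessSeries, n: int) -> int:
    n = int(n)
    if not 0 <= n < series.times.size:
        raise IndexError(f"time index {n} outside grid of size {series.times.size}")
    return n


def gel_layer_change(
    series: ThicknessSeries, n: int, denominator: str = "current"
) -> float:
    """Percent change in gel-layer thickness at time index ``n``.

    With ``denominator="current"`` (default) this is
    ``(T_n - T_0) / T_n * 100``, where ``T_n`` is the replicate-mean
    thickness at the requested grid point; ``denominator="initial"`` uses
    ``T_0`` instead (the conventional swelling ratio).  Returns 0 exactly
    when ``T_n == T_0``; a shrinking film gives a negative percentage.
    """
    n = _index_for(series, n)
    t_n = float(series.mean[n])
    t_0 = float(series.T0)
    if denominator == "current":
        den = t_n
    elif denominator == "initial":
        den = t_0
    else:
        raise ValueError("denominator must be 'current' or 'initial'")
    return (t_n - t_0) / den * 100.0


def cumulative_change(
    series: ThicknessSeries, n: int, denominator: str = "current"
) -> float:
    """Cumulative percent change up to time index ``n`` (``n >= 1``).

    Sum of the per-interval terms ``(T_i - T_0) / T_i * 100`` for
    ``i = 1..n`` (denominator convention as in :func:`gel_layer_change`).
    """
    n = _index_for(series, n)
    if n < 1:
        raise ValueError("cumulative change requires n >= 1")
    return float(
        sum(gel_layer_change(series, i, denominator=denominator) for i in range(1, n + 1))
    )


def plateau_time(
    series: ThicknessSeries, tol: float, denominator: str = "current"
) -> float | None:
    """Earliest time (s) after which the gel-layer change has plateaued.

    The series is considered plateaued from grid point ``k`` onward when
    every successive pair of :func:`gel_layer_change` values from ``k`` to
    the end differs by less than ``tol`` (percent).  Returns ``None`` when
    the curve never settles; a constant series plateaus at ``times[0]``.
    Requires at least three time points.
    """
    if series.times.size < 3:
        raise ValueError("plateau detection requires at least 3 time points")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    g = np.array(
        [gel_layer_change(series, i, denominator=denominator) for i in range(series.times.size)]
    )
    settled = np.abs(np.diff(g)) < tol
    if not settled[-1]:
        return None
    # index of the last unsettled step; plateau starts at the grid point after it
    violations = np.nonzero(~settled)[0]
    k = 0 if violations.size == 0 else int(violations[-1]) + 1
    return float(series.times[k])


def film_front_um(frame: FilmFrame, axis: str = "radial") -> float:
    """Hydrated-front distance (µm) between film boundary and dry core.

    The frame is segmented with a two-threshold (three-class) Otsu split:
    the brightest class is the dry core, the middle class the hydrated
    film annulus, the darkest the background.  ``axis`` selects how the
    front distance is measured:

    * ``"radial"`` (default): difference of area-equivalent radii of the
      film+core and core regions.
    * ``"horizontal"`` / ``"vertical"``: half the width difference along
      the row/column through the core centroid.

    Raises :class:`SegmentationError` when no boundary can be found
    (blank or single-class frames).
    """
    from skimage.filters import threshold_multiotsu

    img = frame.image
    if float(img.max() - img.min()) < 1e-9:
        raise SegmentationError("frame has no contrast; no boundary found")
    try:
        t_lo, t_hi = threshold_multiotsu(img, classes=3)
    except ValueError as exc:  # fewer than 3 grey levels present
        raise SegmentationError(f"could not threshold frame: {exc}") from exc
    outer = img > t_lo  # film + core
    core = img > t_hi
    if core.sum() == 0 or outer.sum() <= core.sum():
        raise SegmentationError("no film annulus outside the core boundary")

    if axis == "radial":
        r_outer = math.sqrt(outer.sum() / math.pi)
        r_core = math.sqrt(core.sum() / math.pi)
        front_px = r_outer - r_core
    elif axis in ("horizontal", "vertical"):
        rows, cols = np.nonzero(core)
        rc, cc = int(round(rows.mean())), int(round(cols.mean()))
        line_outer = outer[rc, :] if axis == "horizontal" else outer[:, cc]
        line_core = core[rc, :] if axis == "horizontal" else core[:, cc]
        front_px = (line_outer.sum() - line_core.sum()) / 2.0
    else:
        raise ValueError("axis must be 'radial', 'horizontal' or 'vertical'")
    return front_px / frame.scale * 1000.0


def thickness_from_frames(
    frames: list[FilmFrame],
    axis: str = "radial",
    formulation_id: str = "frames",
) -> ThicknessSeries:
    """Extract a :class:`ThicknessSeries` from calibrated image frames.

    The first frame defines the initial thickness ``T0``.  Frames whose
    segmentation fails are excluded with a warning rather than aborting
    the whole series.  All frames must share the same pixel calibration.
    """
    if not frames:
        raise ValueError("no frames supplied")
    scale = frames[0].scale
    if any(abs(f.scale - scale) > 1e-9 for f in frames):
        raise ValueError("all frames must share the same px/mm calibration")

    times: list[float] = []
    fronts: list[float] = []
    for f in frames:
        try:
            fronts.append(film_front_um(f, axis=axis))
            times.append(f.timestamp)
        except SegmentationError as exc:
            warnings.warn(
                f"frame at t={f.timestamp:g}s excluded: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
    if not fronts:
        raise SegmentationError("segmentation failed on every frame")
    return ThicknessSeries(
        formulation_id=formulation_id,
        times=np.asarray(times),
        thickness=np.asarray(fronts)[None, :],
    )
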